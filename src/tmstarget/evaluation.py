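"""Quantitative evaluation of stimulation targets.

Covers the full metric battery used to compare targeting algorithms:

* scalp proximity (distance-to-scalp, or sulcal depth as a proxy), with the
  linear conversion of distance differences into stimulation-intensity
  changes (3% per mm at 100% resting motor threshold, scaled by the dosage
  fraction);
* test–retest reliability as the inter-/intra-individual distance ratio —
  intra is the distance between a subject's two session targets, inter the
  mean distance to other subjects' targets; a larger ratio is better, and a
  group-level (identical-for-everyone) target degenerates to intra = 0,
  which is flagged infinite rather than treated as excellent;
* seed connectivity of the target region evaluated on a held-out run;
* E-field engagement metrics computed from externally simulated field maps:
  hotspot extraction (top-x% field magnitude), network specificity of the
  hotspot, field-weighted hotspot seed connectivity, and the
  inter-/intra-individual E-field correlation ratio (for which SMALLER is
  better — the opposite sense to the distance ratio; the output schema
  records this explicitly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectivity import SeedTimecourse, TimeSeriesVolume, _pearson_rows
from .volumes import Mask, ScalarMap, TargetPoint, percentile_threshold


# ---------------------------------------------------------------------------
# Distance -> stimulation intensity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityModel:
    """Linear conversion from distance-to-scalp change to intensity change.

    A 1 mm reduction in distance-to-scalp corresponds to a 3% decrease in
    stimulation intensity at 100% resting motor threshold (RMT); dosing at a
    fraction of RMT scales the slope proportionally (2.7%/mm at 90% RMT).
    """

    pct_per_mm_at_100rmt: float = 3.0
    rmt_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.rmt_fraction <= 1):
            raise ValueError("rmt_fraction must be in (0, 1]")

    @property
    def slope_pct_per_mm(self) -> float:
        return self.pct_per_mm_at_100rmt * self.rmt_fraction


def intensity_reduction(d_ref_mm: float, d_new_mm: float,
                        model: IntensityModel | None = None) -> float:
    """Percent intensity reduction when moving from ``d_ref`` to ``d_new``.

    Positive = the new (shallower) target needs less intensity. Linear and
    antisymmetric in its two distance arguments.
    """
    if d_ref_mm < 0 or d_new_mm < 0:
        raise ValueError("distances must be non-negative")
    model = model or IntensityModel()
    return (d_ref_mm - d_new_mm) * model.slope_pct_per_mm


# ---------------------------------------------------------------------------
# Distance-based reliability
# ---------------------------------------------------------------------------


def reliability_ratio(own_pair: tuple[TargetPoint, TargetPoint],
                      others: Sequence[TargetPoint],
                      ) -> tuple[float, float, float]:
    """(intra mm, inter mm, inter/intra ratio) for one subject.

    ``own_pair`` are the subject's session-1 and session-2 targets; intra is
    their separation. ``others`` are the other subjects' targets already
    expressed in this subject's frame; inter is the mean distance from the
    session-1 self target to them (NaN when empty). intra = 0 yields an
    infinite ratio — the degenerate group-target case, flagged rather than
    rewarded. Larger ratios indicate greater reliability.
    """
    t1, t2 = own_pair
    intra = t1.distance_to(t2)
    inter = (float(np.mean([t1.distance_to(o) for o in others]))
             if others else math.nan)
    if math.isnan(inter):
        ratio = math.nan
    elif intra == 0:
        ratio = math.inf
    else:
        ratio = inter / intra
    return intra, inter, ratio


# ---------------------------------------------------------------------------
# E-field metrics
# ---------------------------------------------------------------------------


@dataclass
class EFieldMap:
    """Simulated E-field magnitudes, on a voxel grid or a vertex list.

    Either wrap a :class:`ScalarMap` (voxel data) or supply explicit
    ``coords`` (n, 3 world mm) and ``values`` (n,) for surface vertices.
    Internal computation is location-set based so both behave identically.
    """

    magnitude: ScalarMap | None = None
    coords: np.ndarray | None = None
    values: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.magnitude is not None:
            idx = self.magnitude.valid.indices()
            self.coords = self.magnitude.grid.voxel_to_world(idx)
            self.values = self.magnitude.value[tuple(idx.T)]
            self._voxel_indices = idx
        else:
            if self.coords is None or self.values is None:
                raise ValueError("need a ScalarMap or coords + values")
            self.coords = np.asarray(self.coords, float).reshape(-1, 3)
            self.values = np.asarray(self.values, float).ravel()
            if len(self.coords) != len(self.values):
                raise ValueError("coords and values length mismatch")
            self._voxel_indices = None
        if (self.values < 0).any():
            raise ValueError("E-field magnitudes must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)


def efield_hotspot(e: EFieldMap, top_percent: float) -> np.ndarray:
    """Indices (into the map's location set) of the top-x% field magnitudes.

    Nearest-rank with ceiling, ties broken by value then location index —
    the same semantics as every other percentile threshold in the package.
    """
    if not (0 < top_percent <= 100):
        raise ValueError("top_percent must be in (0, 100]")
    n = e.n
    if n == 0:
        raise ValueError("E-field map is empty")
    k = int(np.ceil(top_percent / 100.0 * n))
    order = np.lexsort((np.arange(n), -e.values))
    return np.sort(order[:k])


def network_specificity(hotspot: np.ndarray, in_network: np.ndarray,
                        area_weights: np.ndarray | None = None) -> float:
    """Percent of the hotspot area occupied by the target networks.

    ``in_network`` is a boolean per hotspot location (whether the unseen
    run's parcellation assigns it to a target network); ``area_weights``
    optionally weight locations by their represented area (uniform when
    absent, as for isotropic voxels).
    """
    hotspot = np.asarray(hotspot)
    if hotspot.size == 0:
        raise ValueError("hotspot is empty")
    in_network = np.asarray(in_network, bool)
    if in_network.shape[0] != hotspot.shape[0]:
        raise ValueError("in_network must give one flag per hotspot location")
    if area_weights is None:
        area_weights = np.ones(len(hotspot))
    area_weights = np.asarray(area_weights, float)
    total = area_weights.sum()
    if total <= 0:
        raise ValueError("total hotspot area is zero")
    return float(area_weights[in_network].sum() / total * 100.0)


def hotspot_in_network(hotspot: np.ndarray, e: EFieldMap,
                       parcellation_labels: np.ndarray,
                       target_networks: Sequence[int]) -> np.ndarray:
    """Boolean per hotspot location: does its label belong to the targets?

    ``parcellation_labels`` is aligned with the E-field map's location set
    (one label per location).
    """
    labels = np.asarray(parcellation_labels).ravel()
    if len(labels) != e.n:
        raise ValueError("one parcellation label per E-field location required")
    return np.isin(labels[np.asarray(hotspot)], list(target_networks))


def hotspot_seed_fc(hotspot: np.ndarray, e: EFieldMap, ts: TimeSeriesVolume,
                    seed: SeedTimecourse) -> float:
    """Correlation of the E-field-weighted hotspot time course with the seed.

    Each hotspot location contributes its BOLD series weighted by the local
    field strength; the result is invariant to a global rescaling of the
    field map. Requires a grid-backed E-field map so locations map to voxels.
    """
    if e._voxel_indices is None:
        raise ValueError("hotspot_seed_fc requires a voxel-grid E-field map")
    hs = np.asarray(hotspot)
    if hs.size == 0:
        raise ValueError("hotspot is empty")
    vox = e._voxel_indices[hs]
    ok = ts.valid.member[tuple(vox.T)]
    if not ok.any():
        raise ValueError("hotspot does not overlap valid time-series voxels")
    vox = vox[ok]
    w = e.values[hs][ok]
    if w.sum() <= 0:
        w = np.ones(len(vox))
    series = ts.series[tuple(vox.T)]  # (n, T)
    mean_series = w @ series / w.sum()
    r = _pearson_rows(mean_series[None, :], seed.values)[0]
    if np.isnan(r):
        raise ValueError("hotspot mean series has zero variance")
    return float(r)


def efield_reliability(e_run1: EFieldMap, e_run2: EFieldMap,
                       e_others: Sequence[EFieldMap],
                       ) -> tuple[float, float, float]:
    """(intra r, inter r, inter/intra ratio) of E-field maps.

    intra is the correlation between the subject's two run maps; inter the
    mean correlation between run 1 and the other subjects' maps (all maps on
    the subject's location set). For this ratio SMALLER is better: a low
    inter (fields distinct across people) over a high intra (fields
    reproducible within a person) signals reliable, individual-specific
    field engagement.
    """

    def corr(a: EFieldMap, b: EFieldMap) -> float:
        if a.n != b.n:
            raise ValueError("E-field maps cover different location sets")
        if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
            raise ValueError("zero-variance E-field map")
        return float(_pearson_rows(a.values[None, :], b.values)[0])

    intra = corr(e_run1, e_run2)
    if not e_others:
        raise ValueError("need at least one other subject's E-field map")
    inter = float(np.mean([corr(e_run1, o) for o in e_others]))
    ratio = inter / intra if intra != 0 else math.inf
    return intra, inter, ratio


# ---------------------------------------------------------------------------
# Per-subject record
# ---------------------------------------------------------------------------


@dataclass
class EvaluationRecord:
    """Metric bundle for one subject and one algorithm.

    ``reliability_better`` / ``efield_ratio_better`` record the favourable
    direction of each ratio so downstream summaries cannot silently invert
    them.
    """

    subject: str
    algorithm: str
    distance_to_scalp_mm: float = math.nan
    intra_distance_mm: float = math.nan
    inter_distance_mm: float = math.nan
    reliability_ratio: float = math.nan
    seed_fc: float = math.nan
    intensity_reduction_pct: float = math.nan
    efield_intra_r: float = math.nan
    efield_inter_r: float = math.nan
    efield_ratio: float = math.nan
    network_specificity_pct: float = math.nan
    hotspot_seed_fc: float = math.nan
    reliability_better: str = "larger"
    efield_ratio_better: str = "smaller"

    def as_dict(self) -> dict:
        return dict(self.__dict__)
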