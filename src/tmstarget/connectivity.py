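"""Seed time courses and voxelwise functional connectivity.

The targeting algorithms consume a single scalar field: the Pearson
correlation between every voxel's BOLD series and a seed time course. For
deep, low-SNR seed regions such as the subgenual ACC the seed course is not
read out of the region itself but built as a weighted average of gray-matter
voxel series, weighted by a group-level seed-connectivity map (the "group
weight" construction). Voxels inside the stimulation-site mask are excluded
from the average so the seed signal is not contaminated by the region being
targeted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .volumes import Mask, ScalarMap, TargetPoint, VolumeGrid, sphere_mask

WeightMode = Literal["normalized", "absolute"]


@dataclass
class TimeSeriesVolume:
    """A 4D BOLD run: ``T`` frames per voxel on a :class:`VolumeGrid`.

    ``series`` has shape ``(*grid.shape, T)``. ``valid`` marks voxels whose
    series is meaningful (typically the brain mask); constant-in-time voxels
    are detected lazily by the correlation routines and flagged undefined.
    """

    grid: VolumeGrid
    series: np.ndarray
    valid: Mask | None = None

    def __post_init__(self) -> None:
        series = np.asarray(self.series)
        if not np.issubdtype(series.dtype, np.floating):
            series = series.astype(float)  # preserve float32 inputs as-is
        if series.ndim != 4 or series.shape[:3] != self.grid.shape:
            raise ValueError(
                f"series shape {series.shape} does not match grid {self.grid.shape} + T"
            )
        self.series = series
        if self.valid is None:
            self.valid = Mask(self.grid, np.isfinite(series).all(axis=-1))
        else:
            self.grid.require_same(self.valid.grid, "time-series validity mask")

    @property
    def T(self) -> int:
        return self.series.shape[-1]


@dataclass
class WeightMap:
    """Group-level seed weights plus an exclusion mask.

    Weights may be negative (anticorrelated territory contributes with a
    negative sign); ``exclusion`` bars voxels — typically the stimulation-site
    mask — from the weighted average regardless of their weight.
    """

    map: ScalarMap
    exclusion: Mask | None = None

    def __post_init__(self) -> None:
        if self.exclusion is None:
            self.exclusion = Mask(self.map.grid,
                                  np.zeros(self.map.grid.shape, dtype=bool))
        else:
            self.map.grid.require_same(self.exclusion.grid, "exclusion mask")


@dataclass
class SeedTimecourse:
    """A 1D seed signal with provenance."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(values).all():
            raise ValueError("seed time course contains non-finite values")
        self.values = values

    @property
    def T(self) -> int:
        return len(self.values)

    @property
    def zero_variance(self) -> bool:
        return bool(np.ptp(self.values) == 0)


def weighted_seed_timecourse(ts: TimeSeriesVolume, w: WeightMap, gray: Mask,
                             mode: WeightMode = "normalized") -> SeedTimecourse:
    """Weighted average of gray-matter voxel series under a group weight map.

    Contributing voxels are ``gray ∩ w.valid ∩ ts.valid \\ w.exclusion``. In
    ``normalized`` mode (default) each frame is ``Σ wᵢxᵢ(t) / Σ wᵢ``; when the
    weights nearly cancel this is ill-posed and an error points at the
    sign-preserving ``absolute`` mode, ``Σ wᵢxᵢ(t) / Σ |wᵢ|``.
    """
    ts.grid.require_same(w.map.grid, "weight map")
    ts.grid.require_same(gray.grid, "gray mask")
    contributing = (gray.member & w.map.valid.member & ts.valid.member
                    & ~w.exclusion.member)
    if not contributing.any():
        raise ValueError("no contributing voxels: gray ∩ weights \\ exclusion is empty")
    weights = w.map.value[contributing]
    x = ts.series[contributing]  # (n, T)
    wsum = weights.sum()
    if mode == "normalized":
        if abs(wsum) < 1e-10 * np.abs(weights).sum():
            raise ValueError(
                "weights sum to ~0; the normalized weighted mean is undefined — "
                "use mode='absolute' (divide by Σ|w|) instead"
            )
        denom = wsum
    elif mode == "absolute":
        denom = np.abs(weights).sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = weights @ x / denom
    return SeedTimecourse(values, {"mode": mode, "n_voxels": int(contributing.sum())})


def _pearson_rows(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``x`` and the vector ``s``.

    Rows with zero variance get NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    ss = np.sqrt((sc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ sc) / (sx * ss)
    # exactly-constant rows are undefined even when centering leaves
    # rounding-level residuals
    r[(sx == 0) | (np.ptp(x, axis=1) == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def fc_map(ts: TimeSeriesVolume, seed: SeedTimecourse, roi: Mask) -> ScalarMap:
    """Voxelwise Pearson correlation with the seed time course, within an ROI.

    Zero-variance voxels are undefined in the returned map rather than set to
    zero; values are clipped to [-1, 1] against rounding noise.
    """
    if ts.T < 3:
        raise ValueError(f"need at least 3 frames for correlation, got {ts.T}")
    if seed.T != ts.T:
        raise ValueError(f"seed has {seed.T} frames but time series has {ts.T}")
    if seed.zero_variance:
        raise ValueError("seed time course has zero variance")
    ts.grid.require_same(roi.grid, "ROI")
    sel = roi.member & ts.valid.member
    out = np.full(ts.grid.shape, np.nan)
    if sel.any():
        out[sel] = _pearson_rows(ts.series[sel], seed.values)
    return ScalarMap(ts.grid, out, Mask(ts.grid, sel & np.isfinite(out)))


def target_seed_fc(target: TargetPoint, radius_mm: float, ts: TimeSeriesVolume,
                   seed: SeedTimecourse) -> float:
    """Correlation between a spherical target region's mean series and the seed.

    Used to score a target derived in one session against the seed signal of
    another session. ``radius_mm = 0`` degrades to the single nearest voxel.
    """
    region = sphere_mask(ts.grid, target.world_mm, radius_mm)
    sel = region.member & ts.valid.member
    if not sel.any() and radius_mm == 0:
        # radius-0 fallback: nearest voxel to the target point
        vox = np.clip(target.voxel_index, 0, np.array(ts.grid.shape) - 1)
        sel = np.zeros(ts.grid.shape, dtype=bool)
        sel[tuple(vox)] = ts.valid.member[tuple(vox)]
    if not sel.any():
        raise ValueError(
            f"target region (radius {radius_mm} mm) contains no valid voxels"
        )
    mean_series = ts.series[sel].mean(axis=0)
    r = _pearson_rows(mean_series[None, :], seed.values)[0]
    if np.isnan(r):
        raise ValueError("target region series has zero variance")
    return float(r)
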