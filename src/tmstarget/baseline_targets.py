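"""Comparison targeting algorithms: connectome-guided cluster and the cone.

The cluster algorithm thresholds the seed-connectivity map inside the
anatomical search mask and returns the centroid of the largest surviving
connected component; nothing constrains it toward the scalp, so its targets
can land deep in a sulcus. Its retention threshold is tuned per individual by
leave-one-out cross-validation (:func:`loocv_cluster_threshold`).

The cone algorithm scans candidate sites on the brain surface inside the
search mask and scores each with a distance-weighted average of the
connectivity map inside a 12 mm sphere — the weight profile decays linearly
from the site (a "cone" of concentric shells at 2, 4, 7, 9 and 12 mm,
normalised to mean one), mimicking the spatial falloff of stimulation
effects. By construction its targets hug the brain surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .connectivity import SeedTimecourse, TimeSeriesVolume, target_seed_fc
from .volumes import (
    Connectivity,
    Mask,
    ScalarMap,
    TargetPoint,
    boundary_voxels,
    component_centroid,
    connected_components,
    percentile_threshold,
)

logger = logging.getLogger("tmstarget")

Direction = Literal["negative", "positive"]


# ---------------------------------------------------------------------------
# Cluster algorithm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSettings:
    """Retention threshold for the cluster algorithm.

    ``fc_percent`` keeps the top x% most favourable connectivity voxels
    (percentile dialect, matching the LOOCV search space); ``absolute_r``
    switches to a plain correlation cutoff instead.
    """

    fc_percent: float = 10.0
    direction: Direction = "negative"
    absolute_r: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fc_percent <= 100):
            raise ValueError("fc_percent must be in (0, 100]")
        if self.direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")


def cluster_target(fc: ScalarMap, mask: Mask, s: ClusterSettings, *,
                   connectivity: Connectivity = 26) -> TargetPoint:
    """Centroid of the largest component of the thresholded connectivity map.

    Component labels are ordered by decreasing size with ties broken by the
    lowest voxel index, so the "largest component" choice is deterministic.
    """
    if mask.is_empty():
        raise ValueError("mask is empty")
    if s.absolute_r is not None:
        sel = mask.member & fc.valid.member
        keep = (fc.value <= s.absolute_r) if s.direction == "negative" \
            else (fc.value >= s.absolute_r)
        thresholded = Mask(fc.grid, sel & keep)
        if thresholded.is_empty():
            raise ValueError(
                f"absolute threshold r={s.absolute_r} retains no voxels"
            )
    else:
        direction = "lowest" if s.direction == "negative" else "highest"
        thresholded = percentile_threshold(fc, mask, s.fc_percent, direction)
    labels = connected_components(thresholded, connectivity)
    target = component_centroid(labels, 1, fc.grid)  # label 1 = largest
    target.meta.update(algorithm="cluster", fc_percent=s.fc_percent,
                       direction=s.direction)
    vox = np.flatnonzero(labels.label.ravel() == 1)
    target.meta["fc_value"] = float(fc.value.ravel()[vox].mean())
    return target


def loocv_cluster_threshold(
    subjects: Sequence[tuple[ScalarMap, TimeSeriesVolume, SeedTimecourse, Mask]],
    candidate_percents: Sequence[float],
    direction: Direction = "negative",
    eval_radius_mm: float = 5.0,
    connectivity: Connectivity = 26,
) -> list[float]:
    """Leave-one-individual-out selection of the cluster retention threshold.

    Each subject is a tuple ``(fc_train, ts_eval, seed_eval, mask)``: the
    connectivity map targets are derived from, the held-out run used for
    evaluation, the seed time course of that run, and the search mask. For
    each held-out subject, every candidate threshold is applied to all
    *other* subjects; the threshold whose cluster targets achieve the most
    favourable mean evaluation connectivity (most negative for the depression
    direction) is assigned to the held-out subject. A threshold at which any
    training subject yields no valid target is skipped with a log entry.
    """
    if len(subjects) < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    if not candidate_percents:
        raise ValueError("candidate_percents must be non-empty")

    n = len(subjects)
    # score[j][p] = evaluation FC for subject j at threshold p (NaN = failed)
    scores = np.full((n, len(candidate_percents)), np.nan)
    for j, (fc_train, ts_eval, seed_eval, mask) in enumerate(subjects):
        for k, p in enumerate(candidate_percents):
            try:
                t = cluster_target(fc_train, mask,
                                   ClusterSettings(p, direction),
                                   connectivity=connectivity)
                scores[j, k] = target_seed_fc(t, eval_radius_mm, ts_eval,
                                              seed_eval)
            except ValueError as exc:
                logger.info("LOOCV: subject %d threshold %s%% skipped (%s)",
                            j, p, exc)

    chosen: list[float] = []
    sign = 1.0 if direction == "negative" else -1.0
    for i in range(n):
        train = np.delete(scores, i, axis=0)
        usable = ~np.isnan(train).any(axis=0)
        if not usable.any():
            raise ValueError(
                f"no candidate threshold valid for all training subjects "
                f"(held-out subject {i})"
            )
        mean_fc = np.where(usable, sign * np.nanmean(train, axis=0), np.inf)
        chosen.append(float(candidate_percents[int(np.argmin(mean_fc))]))
    return chosen


# ---------------------------------------------------------------------------
# Cone algorithm
# ---------------------------------------------------------------------------


def _linear_decay(outer_radius: float) -> Callable[[np.ndarray], np.ndarray]:
    def w(d: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, 1.0 - np.asarray(d, float) / outer_radius)
    return w


@dataclass(frozen=True)
class ConeKernel:
    """Distance-weighting profile of the cone score.

    ``radii_mm`` are the documented shell radii; the outermost defines the
    sphere of integration. The default ``weight_at`` decays linearly from a
    peak at the centre to zero at the outer radius (a continuous reading of
    the shell profile); a per-shell-constant profile can be supplied instead.
    Realized voxel weights are normalised to mean one over the voxels inside
    the outer sphere.
    """

    radii_mm: tuple[float, ...] = (2.0, 4.0, 7.0, 9.0, 12.0)
    weight_at: Callable[[np.ndarray], np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_mm)
        if not radii or any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
            raise ValueError("radii_mm must be strictly increasing and positive")
        object.__setattr__(self, "radii_mm", radii)
        if self.weight_at is None:
            object.__setattr__(self, "weight_at", _linear_decay(radii[-1]))

    @property
    def outer_radius(self) -> float:
        return self.radii_mm[-1]

    def realized_weights(self, distances_mm: np.ndarray) -> np.ndarray:
        """Mean-one-normalised weights for voxels at the given distances.

        All distances must lie within the outer radius. Weights from the raw
        profile must be non-negative and non-increasing with distance.
        """
        d = np.asarray(distances_mm, float)
        if d.size == 0:
            raise ValueError("no voxels inside the cone")
        w = np.asarray(self.weight_at(d), float)
        if (w < 0).any():
            raise ValueError("cone weights must be non-negative")
        m = w.mean()
        if m <= 0:
            raise ValueError("cone weights are all zero inside the sphere")
        return w / m


def surface_seeds(mask: Mask, brain: Mask, spacing_mm: float, *,
                  connectivity: Connectivity = 6) -> list[TargetPoint]:
    """Brain-surface voxels inside the mask, thinned to a minimum spacing.

    Surface voxels are mask voxels on the exterior boundary of the brain
    (adjacent to non-brain). Thinning is greedy farthest-point: start from the
    lowest voxel index, then repeatedly add the remaining surface voxel
    farthest from the selected set (ties by lowest voxel index) until no
    remaining voxel is at least ``spacing_mm`` from every selected one.
    ``spacing_mm = 0`` retains every surface voxel.
    """
    mask.grid.require_same(brain.grid, "brain mask")
    surf = mask & boundary_voxels(brain, connectivity)
    idx = surf.indices()
    if len(idx) == 0:
        logger.warning("surface_seeds: mask contains no brain-surface voxels")
        return []
    world = surf.grid.voxel_to_world(idx)

    def make_point(i: int) -> TargetPoint:
        return TargetPoint(world[i], tuple(idx[i]), {"kind": "surface_seed"})

    if spacing_mm <= 0:
        return [make_point(i) for i in range(len(idx))]

    selected = [0]  # indices sorted in C order; 0 is the lowest voxel index
    min_d = np.linalg.norm(world - world[0], axis=1)
    while True:
        far = float(min_d.max())
        if far < spacing_mm:
            break
        cand = int(np.flatnonzero(min_d == far)[0])  # lowest index among ties
        selected.append(cand)
        min_d = np.minimum(min_d, np.linalg.norm(world - world[cand], axis=1))
    return [make_point(i) for i in selected]


def cone_target(fc: ScalarMap, seeds: Sequence[TargetPoint],
                kernel: ConeKernel | None = None,
                direction: Direction = "negative") -> TargetPoint:
    """Seed with the most favourable cone-weighted average connectivity.

    Each seed's score is the weighted mean of defined connectivity values
    within the kernel's outer sphere; seeds with no defined voxel in reach are
    skipped with a log entry. The most negative score wins (most positive for
    ``direction='positive'``); exact ties go to the earliest seed in the input
    (canonical) order.
    """
    if not seeds:
        raise ValueError("no seeds supplied")
    kernel = kernel or ConeKernel()
    valid_idx = fc.valid.indices()
    if len(valid_idx) == 0:
        raise ValueError("connectivity map has no defined voxels")
    valid_world = fc.grid.voxel_to_world(valid_idx)
    valid_vals = fc.value[tuple(valid_idx.T)]

    best_i, best_score = None, None
    sign = 1.0 if direction == "negative" else -1.0
    for i, seed in enumerate(seeds):
        d = np.linalg.norm(valid_world - seed.world_mm, axis=1)
        inside = d <= kernel.outer_radius
        if not inside.any():
            logger.info("cone: seed %d has no defined voxels within %.1f mm; "
                        "skipped", i, kernel.outer_radius)
            continue
        w = kernel.realized_weights(d[inside])
        score = float(w @ valid_vals[inside] / w.sum())
        # relative tolerance so rounding-level differences count as ties,
        # which then resolve to the earliest seed in canonical order
        if best_score is None or sign * score < sign * best_score \
                - 1e-12 * max(1.0, abs(best_score)):
            best_i, best_score = i, score
    if best_i is None:
        raise ValueError("every seed's cone contained no defined voxels")
    winner = seeds[best_i]
    out = TargetPoint(winner.world_mm.copy(), winner.voxel_index,
                      dict(winner.meta))
    out.meta.update(algorithm="cone", cone_score=best_score,
                    direction=direction, fc_value=best_score)
    return out
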