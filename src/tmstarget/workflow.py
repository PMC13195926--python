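"""End-to-end targeting and evaluation runs.

Per subject and session: build the seed time course (group-weight
construction), compute the voxelwise connectivity map, derive a target with
each enabled algorithm, and then cross-evaluate with the session-swap
contract — targets derived from one session are scored against the other
session's data, the roles are reversed, and the two values averaged.
Failures quarantine the affected subject with a logged reason; the run
continues for the rest of the cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .baseline_targets import cluster_target, cone_target, surface_seeds
from .connectivity import (
    SeedTimecourse,
    TimeSeriesVolume,
    WeightMap,
    fc_map,
    target_seed_fc,
    weighted_seed_timecourse,
)
from .evaluation import EvaluationRecord, intensity_reduction, reliability_ratio
from .io import RunConfig, target_row, targets_to_frame
from .phantom import PhantomSubject
from .tree_target import tree_based_target
from .volumes import LabelMap, Mask, ScalarMap, TargetPoint

logger = logging.getLogger("tmstarget")


@dataclass
class SubjectData:
    """The per-subject inputs every targeting algorithm consumes.

    ``depth`` is a distance-to-scalp (or sulcal-depth) map where smaller is
    closer to the scalp. ``seed_timecourses``, when provided, override the
    group-weight construction (useful when the seed signal is known, as in
    phantoms, or precomputed externally).
    """

    subject: str
    parcellation: LabelMap
    depth: ScalarMap
    gray: Mask
    search_mask: Mask
    sessions: list[TimeSeriesVolume]
    target_networks: tuple[int, ...]
    weight_map: WeightMap | None = None
    seed_timecourses: list[SeedTimecourse] | None = None

    @classmethod
    def from_phantom(cls, subject: PhantomSubject, subject_id: str,
                     use_true_seed: bool = False) -> "SubjectData":
        return cls(
            subject=subject_id,
            parcellation=subject.parcellation,
            depth=subject.depth,
            gray=subject.gray,
            search_mask=subject.search_mask,
            sessions=subject.sessions,
            target_networks=subject.target_networks,
            weight_map=subject.weight_map,
            seed_timecourses=(subject.seed_timecourses if use_true_seed
                              else None),
        )


@dataclass
class WorkflowResult:
    targets: pd.DataFrame
    metrics: pd.DataFrame
    quarantined: dict[str, str] = field(default_factory=dict)


def _seed_for(data: SubjectData, session: int,
              config: RunConfig) -> SeedTimecourse:
    if data.seed_timecourses is not None:
        return data.seed_timecourses[session]
    if data.weight_map is None:
        raise ValueError(f"subject {data.subject}: no weight map and no "
                         "precomputed seed time courses")
    return weighted_seed_timecourse(data.sessions[session], data.weight_map,
                                    data.gray)


def derive_targets(data: SubjectData, session: int,
                   config: RunConfig) -> dict[str, TargetPoint]:
    """One target per enabled algorithm, from one session's run."""
    ts = data.sessions[session]
    seed = _seed_for(data, session, config)
    fc = fc_map(ts, seed, data.gray)
    direction = config.threshold_grid.fc_direction
    out: dict[str, TargetPoint] = {}
    if "tree" in config.algorithms:
        target, _ = tree_based_target(
            data.parcellation, fc, data.depth, data.search_mask,
            data.target_networks, config.threshold_grid,
            connectivity=config.connectivity)
        out["tree"] = target
    if "cluster" in config.algorithms:
        out["cluster"] = cluster_target(fc, data.search_mask, config.cluster,
                                        connectivity=config.connectivity)
    if "cone" in config.algorithms:
        seeds = surface_seeds(data.search_mask, data.gray,
                              config.cone_seed_spacing_mm)
        out["cone"] = cone_target(fc, seeds, config.cone_kernel(), direction)
    return out


def sample_scalar(map: ScalarMap, point: TargetPoint) -> float:
    """Value of a scalar map at the defined voxel nearest to a point.

    Targets are centroids and can fall on voxels where the map is undefined
    (e.g., just off the gray-matter ribbon); the nearest defined voxel is
    then used.
    """
    vox = tuple(np.clip(point.voxel_index, 0, np.array(map.grid.shape) - 1))
    if map.valid.member[vox]:
        return float(map.value[vox])
    idx = map.valid.indices()
    if len(idx) == 0:
        raise ValueError("scalar map has no defined voxels")
    tree = cKDTree(map.grid.voxel_to_world(idx))
    _, i = tree.query(point.world_mm)
    return float(map.value[tuple(idx[int(i)])])


def run_cohort(cohort: list[SubjectData], config: RunConfig | None = None,
               ) -> WorkflowResult:
    """Derive targets for every subject/session and cross-evaluate.

    Subjects must share a common frame (phantom cohorts do by construction;
    real cohorts require caller-side registration). Each subject needs at
    least two sessions for the swap-and-average metrics; the distance and
    connectivity metrics average the (derive-on-A, evaluate-on-B) and
    (derive-on-B, evaluate-on-A) values, and the reliability ratio compares
    within- to between-subject target scatter.
    """
    config = config or RunConfig()
    shash = config.settings_hash

    per_subject: dict[str, dict[int, dict[str, TargetPoint]]] = {}
    quarantined: dict[str, str] = {}
    rows = []
    for data in cohort:
        if len(data.sessions) < 2:
            quarantined[data.subject] = "fewer than 2 sessions"
            logger.warning("subject %s quarantined: fewer than 2 sessions",
                           data.subject)
            continue
        try:
            sessions = {s: derive_targets(data, s, config) for s in (0, 1)}
        except ValueError as exc:
            quarantined[data.subject] = str(exc)
            logger.warning("subject %s quarantined: %s", data.subject, exc)
            continue
        per_subject[data.subject] = sessions
        for s, targets in sessions.items():
            for t in targets.values():
                rows.append(target_row(data.subject, f"ses-{s + 1}", t, shash))

    records: list[EvaluationRecord] = []
    by_id = {d.subject: d for d in cohort}
    for subject, sessions in per_subject.items():
        data = by_id[subject]
        rec_by_alg: dict[str, EvaluationRecord] = {}
        for alg in config.algorithms:
            t1, t2 = sessions[0][alg], sessions[1][alg]
            rec = EvaluationRecord(subject=subject, algorithm=alg)
            # scalp proximity: evaluate each session's target, average
            rec.distance_to_scalp_mm = float(np.mean(
                [sample_scalar(data.depth, t) for t in (t1, t2)]))
            # reliability vs the other subjects' session-1 targets
            others = [per_subject[o][0][alg] for o in per_subject
                      if o != subject]
            intra, inter, ratio = reliability_ratio((t1, t2), others)
            rec.intra_distance_mm = intra
            rec.inter_distance_mm = inter
            rec.reliability_ratio = ratio
            # seed FC on the held-out session, swapped and averaged
            try:
                seeds = [_seed_for(data, s, config) for s in (0, 1)]
                fc12 = target_seed_fc(t1, config.eval_radius_mm,
                                      data.sessions[1], seeds[1])
                fc21 = target_seed_fc(t2, config.eval_radius_mm,
                                      data.sessions[0], seeds[0])
                rec.seed_fc = float((fc12 + fc21) / 2.0)
            except ValueError as exc:
                logger.warning("subject %s %s: seed FC unavailable (%s)",
                               subject, alg, exc)
            rec_by_alg[alg] = rec
        ref = rec_by_alg.get(config.reference_algorithm)
        for alg, rec in rec_by_alg.items():
            if ref is not None and alg != config.reference_algorithm:
                rec.intensity_reduction_pct = intensity_reduction(
                    ref.distance_to_scalp_mm, rec.distance_to_scalp_mm,
                    config.intensity)
            records.append(rec)

    metrics = pd.DataFrame([r.as_dict() for r in records])
    targets = targets_to_frame(rows) if rows else pd.DataFrame(
        columns=["subject", "session", "algorithm", "x_mm", "y_mm", "z_mm",
                 "n_candidates", "settings_hash"])
    return WorkflowResult(targets=targets, metrics=metrics,
                          quarantined=quarantined)
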