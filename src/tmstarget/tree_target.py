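"""Tree-based consensus target localization.

Fixed thresholds on a near-scalp map and a seed-connectivity map do not
transfer across individuals, scanners or disorders: connectivity magnitudes
shift with acquisition and preprocessing, and cortical folding varies. The
algorithm here sidesteps threshold selection by sweeping both thresholds over
a pre-declared range and taking a consensus:

Phase 1
    Build a personalized ROI: voxels of the individual-specific target
    networks (e.g., dorsal attention + salience/ventral attention for
    depression) inside an anatomical search mask (e.g., the DLPFC
    union-of-spheres).
Phase 2
    For each near-scalp percentile (default 5–10% in steps of 1), keep the
    ROI voxels closest to the scalp; then sweep the connectivity percentile
    from most stringent to most lenient (default 5–100% in steps of 5). At
    each level, connected components are extracted and their centroids
    computed. Because the threshold masks are nested, a stricter component is
    always wholly contained in one lenient component, so the centroids form a
    forest: components at the strictest level are leaves, and a component that
    swallows several stricter components becomes their merge parent.
    Candidate targets are the leaves plus every parent with at least two
    children — the centroids carrying the strictest defensible thresholds.
Phase 3
    The final target is the candidate closest on average (Euclidean, mm) to
    all other candidates — a medoid-style consensus over the whole forest.

The procedure is fully deterministic; every tie is broken by an explicit
total order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .volumes import (
    Connectivity,
    LabelMap,
    Mask,
    ScalarMap,
    TargetPoint,
    component_centroid,
    connected_components,
    percentile_threshold,
)

logger = logging.getLogger("tmstarget")

FcDirection = Literal["negative", "positive"]


@dataclass(frozen=True)
class ThresholdGrid:
    """The two threshold sweeps and the favourable connectivity direction.

    ``depth_percents`` select the top-x% of ROI voxels nearest the scalp (or
    gyral crown); ``fc_percents`` select the top-x% most negatively (or, for
    ``fc_direction='positive'``, most positively) correlated voxels.
    Both lists must be strictly increasing; connectivity percentiles are
    iterated stringent -> lenient so leaves are built first.
    """

    depth_percents: tuple[float, ...] = (5, 6, 7, 8, 9, 10)
    fc_percents: tuple[float, ...] = tuple(range(5, 101, 5))
    fc_direction: FcDirection = "negative"

    def __post_init__(self) -> None:
        for name, seq in (("depth_percents", self.depth_percents),
                          ("fc_percents", self.fc_percents)):
            seq = tuple(float(p) for p in seq)
            if not seq or any(not 0 < p <= 100 for p in seq):
                raise ValueError(f"{name} must be within (0, 100]")
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, seq)
        if self.fc_direction not in ("negative", "positive"):
            raise ValueError("fc_direction must be 'negative' or 'positive'")

    @property
    def fc_threshold_direction(self) -> str:
        """Percentile direction for :func:`percentile_threshold`."""
        return "lowest" if self.fc_direction == "negative" else "highest"


@dataclass
class TreeNode:
    """One connected component at one (depth %, fc %) threshold pair."""

    centroid: TargetPoint
    fc_percent: float
    depth_percent: float
    voxels: np.ndarray  # sorted flat indices of the component
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_merge(self) -> bool:
        return len(self.children) >= 2

    def descend(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.descend()


@dataclass
class CandidateForest:
    """All trees across all depth thresholds, plus the candidate target set."""

    roots: dict[float, list[TreeNode]]  # depth_percent -> roots
    candidates: list[TargetPoint]

    def all_nodes(self) -> Iterable[TreeNode]:
        for roots in self.roots.values():
            for r in roots:
                yield from r.descend()

    def to_dict(self) -> dict:
        """JSON-serialisable audit dump of the whole forest."""

        def node_dict(n: TreeNode) -> dict:
            return {
                "centroid_mm": [float(v) for v in n.centroid.world_mm],
                "fc_percent": n.fc_percent,
                "depth_percent": n.depth_percent,
                "n_voxels": int(len(n.voxels)),
                "children": [node_dict(c) for c in n.children],
            }

        return {
            "trees": {str(d): [node_dict(r) for r in roots]
                      for d, roots in self.roots.items()},
            "candidates": [
                {"world_mm": [float(v) for v in c.world_mm], "meta": c.meta}
                for c in self.candidates
            ],
        }


# ---------------------------------------------------------------------------
# Phase 1: personalized ROI
# ---------------------------------------------------------------------------


def personalized_roi(parcellation: LabelMap, target_networks: Iterable[int],
                     anatomical_mask: Mask) -> Mask:
    """Target-network voxels of the individual parcellation within a search mask."""
    networks = sorted({int(n) for n in target_networks})
    if not networks:
        raise ValueError("target_networks must be non-empty")
    parcellation.grid.require_same(anatomical_mask.grid, "anatomical mask")
    roi = parcellation.mask_of(networks) & anatomical_mask
    if roi.is_empty():
        raise ValueError(
            f"no target-network voxels in mask (networks {networks}): "
            "degenerate subject"
        )
    return roi


# ---------------------------------------------------------------------------
# Phase 2: forest construction
# ---------------------------------------------------------------------------


def build_forest(fc: ScalarMap, depth: ScalarMap, roi: Mask,
                 grid_spec: ThresholdGrid, *,
                 connectivity: Connectivity = 26,
                 dedup_tolerance_mm: float | None = None) -> CandidateForest:
    """Sweep both thresholds and assemble the candidate forest.

    For each near-scalp percentile the ROI shrinks to its shallowest voxels;
    the connectivity percentile then sweeps stringent -> lenient, producing
    nested masks whose connected components grow and merge. A level-``p`` node
    becomes the parent of every previous-level node whose component is a voxel
    subset of its own (subset testing is exact; nested masks guarantee each
    stricter component maps into exactly one lenient component).

    Candidates are leaves plus merge parents, deduplicated within
    ``dedup_tolerance_mm`` (default: half the smallest voxel edge) so a
    centroid rediscovered at several depth thresholds votes once in Phase 3.
    """
    if roi.is_empty():
        raise ValueError("ROI is empty")
    fc.grid.require_same(roi.grid, "ROI")
    fc.grid.require_same(depth.grid, "depth map")
    if dedup_tolerance_mm is None:
        dedup_tolerance_mm = 0.5 * float(fc.grid.voxel_size.min())

    fc_dir = grid_spec.fc_threshold_direction
    roots: dict[float, list[TreeNode]] = {}
    candidates: list[TargetPoint] = []

    for d in grid_spec.depth_percents:
        try:
            near = percentile_threshold(depth, roi, d, "lowest")
        except ValueError:
            logger.info("depth threshold %s%%: no defined voxels; skipped", d)
            continue
        if (near.member & fc.valid.member).sum() == 0:
            logger.info("depth threshold %s%%: no valid FC voxels; skipped", d)
            continue

        prev_nodes: list[TreeNode] = []
        depth_roots: list[TreeNode] = []
        for p in grid_spec.fc_percents:  # stringent -> lenient
            mask_p = percentile_threshold(fc, near, p, fc_dir)
            labels = connected_components(mask_p, connectivity)
            flat_labels = labels.label.ravel()
            level_nodes: list[TreeNode] = []
            for lab in labels.labels:
                vox = np.flatnonzero(flat_labels == lab)
                cent = component_centroid(labels, int(lab), fc.grid)
                cent.meta.update(
                    depth_percent=float(d), fc_percent=float(p),
                    fc_value=float(fc.value.ravel()[vox].mean()),
                )
                node = TreeNode(cent, float(p), float(d), vox)
                # adopt every stricter component contained in this one
                for child in prev_nodes:
                    if child.parent is None and flat_labels[child.voxels[0]] == lab:
                        if not np.all(flat_labels[child.voxels] == lab):
                            raise AssertionError(
                                "nested threshold masks produced a split "
                                "component; connectivity is inconsistent"
                            )
                        child.parent = node
                        node.children.append(child)
                level_nodes.append(node)
            orphans = [n for n in prev_nodes if n.parent is None]
            if orphans:  # cannot happen with nested masks; guard regardless
                raise AssertionError("stricter component vanished at lenient level")
            prev_nodes = level_nodes
        depth_roots = prev_nodes  # nodes at the most lenient level are roots
        roots[float(d)] = depth_roots
        for root in depth_roots:
            for node in root.descend():
                if node.is_leaf or node.is_merge:
                    tp = TargetPoint(node.centroid.world_mm.copy(),
                                     node.centroid.voxel_index,
                                     dict(node.centroid.meta))
                    tp.meta["kind"] = "leaf" if node.is_leaf else "merge"
                    candidates.append(tp)

    if not roots:
        raise ValueError("every threshold combination produced an empty mask")

    candidates = _deduplicate(candidates, dedup_tolerance_mm)
    return CandidateForest(roots, candidates)


def _deduplicate(candidates: list[TargetPoint], tol_mm: float) -> list[TargetPoint]:
    """Drop candidates within ``tol_mm`` of an earlier one (generation order)."""
    kept: list[TargetPoint] = []
    for c in candidates:
        if all(c.distance_to(k) > tol_mm for k in kept):
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Phase 3: consensus
# ---------------------------------------------------------------------------


def consensus_target(candidates: list[TargetPoint],
                     fc_direction: FcDirection = "negative") -> TargetPoint:
    """The candidate with the smallest mean Euclidean distance to all others.

    A single candidate is returned as-is. Exact ties on mean distance are
    broken by the more favourable connectivity value recorded on the
    candidate (more negative for ``fc_direction='negative'``, more positive
    otherwise), then by lexicographic voxel index — a deterministic total
    order.
    """
    if not candidates:
        raise ValueError("no candidates to choose from")
    if len(candidates) == 1:
        return candidates[0]
    pts = np.array([c.world_mm for c in candidates])
    dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    mean_d = dists.sum(axis=1) / (len(candidates) - 1)
    best = mean_d.min()
    tied = [i for i in range(len(candidates)) if mean_d[i] <= best + 1e-9]

    def sort_key(i: int):
        fc = candidates[i].meta.get("fc_value", 0.0)
        favour = fc if fc_direction == "negative" else -fc
        return (favour, candidates[i].voxel_index)

    winner = min(tied, key=sort_key)
    out = candidates[winner]
    out.meta["mean_candidate_distance_mm"] = float(mean_d[winner])
    out.meta["n_candidates"] = len(candidates)
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def tree_based_target(parcellation: LabelMap, fc: ScalarMap, depth: ScalarMap,
                      anatomical_mask: Mask, target_networks: Iterable[int],
                      grid_spec: ThresholdGrid | None = None, *,
                      connectivity: Connectivity = 26,
                      dedup_tolerance_mm: float | None = None,
                      ) -> tuple[TargetPoint, CandidateForest]:
    """Run all three phases and return the target with its audit forest."""
    grid_spec = grid_spec or ThresholdGrid()
    roi = personalized_roi(parcellation, target_networks, anatomical_mask)
    forest = build_forest(fc, depth, roi, grid_spec,
                          connectivity=connectivity,
                          dedup_tolerance_mm=dedup_tolerance_mm)
    target = consensus_target(forest.candidates, grid_spec.fc_direction)
    target.meta.setdefault("algorithm", "tree")
    target.meta["depth_percents"] = list(grid_spec.depth_percents)
    target.meta["fc_percents"] = list(grid_spec.fc_percents)
    target.meta["fc_direction"] = grid_spec.fc_direction
    return target, forest
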