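"""Voxel-grid geometry and mask algebra.

Everything downstream — seed connectivity, the tree-consensus targeting
algorithm, the cluster/cone baselines and the evaluation metrics — operates on
scalar, label and boolean images defined on a common 3D lattice with a
voxel-index -> world-millimetre affine. This module provides those containers
(:class:`VolumeGrid`, :class:`Mask`, :class:`ScalarMap`, :class:`LabelMap`,
:class:`TargetPoint`) and the primitive spatial operations: spherical ROIs,
nearest-rank percentile thresholds, 3D connected components, component
centroids and distance-to-scalp maps.

Conventions
-----------
* World coordinates are millimetres in the frame of the grid affine
  (RAS-oriented affines are typical but nothing here requires them).
* Voxel indices are 0-based ``(i, j, k)`` tuples.
* Percentile thresholds use the nearest-rank rule with a ceiling, taken
  relative to the ROI they are applied within; ties at the cutoff are broken
  by value and then by flat voxel index, so every threshold mask is a
  deterministic function of its inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

logger = logging.getLogger("tmstarget")

Connectivity = Literal[6, 18, 26]

#: scipy binary structures for 6/18/26 neighbourhoods in 3D
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice with an affine mapping voxel indices to world mm.

    Parameters
    ----------
    shape:
        Number of voxels along each axis (three positive integers).
    affine:
        4x4 homogeneous transform taking 0-based voxel indices to world
        coordinates in millimetres. Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length in mm along each voxel axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (``(..., 3)``) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def all_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1)
        return self.voxel_to_world(ijk)

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} grid mismatch: shapes {self.shape} vs {other.shape}"
            )


def isotropic_grid(shape: tuple[int, int, int], voxel_mm: float = 1.0,
                   origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> VolumeGrid:
    """Convenience constructor: axis-aligned isotropic grid."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = origin_mm
    return VolumeGrid(tuple(shape), affine)


@dataclass
class Mask:
    """Boolean per-voxel membership on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    member: np.ndarray

    def __post_init__(self) -> None:
        member = np.asarray(self.member, dtype=bool)
        if member.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {member.shape} does not match grid {self.grid.shape}"
            )
        self.member = member

    @property
    def count(self) -> int:
        return int(self.member.sum())

    def is_empty(self) -> bool:
        return not self.member.any()

    def indices(self) -> np.ndarray:
        """Member voxel indices as an ``(n, 3)`` int array, in C order."""
        return np.argwhere(self.member)

    def world_coords(self) -> np.ndarray:
        return self.grid.voxel_to_world(self.indices())

    # -- set algebra (results share the grid) --
    def __and__(self, other: "Mask") -> "Mask":
        self.grid.require_same(other.grid, "mask")
        return Mask(self.grid, self.member & other.member)

    def __or__(self, other: "Mask") -> "Mask":
        self.grid.require_same(other.grid, "mask")
        return Mask(self.grid, self.member | other.member)

    def __sub__(self, other: "Mask") -> "Mask":
        self.grid.require_same(other.grid, "mask")
        return Mask(self.grid, self.member & ~other.member)

    def __invert__(self) -> "Mask":
        return Mask(self.grid, ~self.member)


@dataclass
class ScalarMap:
    """Per-voxel float values with an explicit validity mask.

    Voxels outside ``valid`` are undefined: they are excluded from every
    threshold and statistic rather than treated as zero.
    """

    grid: VolumeGrid
    value: np.ndarray
    valid: Mask | None = None

    def __post_init__(self) -> None:
        value = np.asarray(self.value, dtype=float)
        if value.shape != self.grid.shape:
            raise ValueError(
                f"value shape {value.shape} does not match grid {self.grid.shape}"
            )
        self.value = value
        if self.valid is None:
            self.valid = Mask(self.grid, np.isfinite(value))
        else:
            self.grid.require_same(self.valid.grid, "validity mask")

    def negated(self) -> "ScalarMap":
        return ScalarMap(self.grid, -self.value, self.valid)


@dataclass
class LabelMap:
    """Non-negative integer labels per voxel; 0 is background."""

    grid: VolumeGrid
    label: np.ndarray

    def __post_init__(self) -> None:
        label = np.asarray(self.label)
        if not np.issubdtype(label.dtype, np.integer):
            if not np.all(label == np.round(label)):
                raise ValueError("label volume contains non-integer values")
            label = label.astype(np.int32)
        if label.min() < 0:
            raise ValueError("labels must be non-negative")
        if label.shape != self.grid.shape:
            raise ValueError(
                f"label shape {label.shape} does not match grid {self.grid.shape}"
            )
        self.label = label

    @property
    def labels(self) -> np.ndarray:
        """Sorted distinct non-background labels."""
        u = np.unique(self.label)
        return u[u > 0]

    def mask_of(self, labels: Iterable[int]) -> Mask:
        return Mask(self.grid, np.isin(self.label, list(labels)))


@dataclass
class TargetPoint:
    """A stimulation-site location in world mm with provenance metadata."""

    world_mm: np.ndarray
    voxel_index: tuple[int, int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.world_mm = np.asarray(self.world_mm, dtype=float)
        if self.world_mm.shape != (3,):
            raise ValueError("world_mm must be 3 floats")
        self.voxel_index = tuple(int(i) for i in self.voxel_index)

    @classmethod
    def from_world(cls, grid: VolumeGrid, world_mm: np.ndarray,
                   meta: dict | None = None) -> "TargetPoint":
        vox = np.round(grid.world_to_voxel(world_mm)).astype(int)
        return cls(np.asarray(world_mm, float), tuple(vox), dict(meta or {}))

    def distance_to(self, other: "TargetPoint") -> float:
        return float(np.linalg.norm(self.world_mm - other.world_mm))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def sphere_mask(grid: VolumeGrid, center_mm, radius_mm: float) -> Mask:
    """Voxels whose centre lies within ``radius_mm`` of ``center_mm``.

    A voxel belongs to the sphere iff the Euclidean distance from its world
    centre to ``center_mm`` is <= ``radius_mm``. Radius 0 selects at most the
    single voxel whose centre coincides with the point. A centre outside the
    grid with a small radius yields an empty mask with a warning, not an
    error, so union-of-spheres ROIs degrade gracefully near the field of view
    edge.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    center_mm = np.asarray(center_mm, dtype=float)

    # bounding box in voxel space to avoid scanning the full grid
    cv = grid.world_to_voxel(center_mm)
    pad = radius_mm / grid.voxel_size.min() + 1.5
    lo = np.maximum(np.floor(cv - pad).astype(int), 0)
    hi = np.minimum(np.ceil(cv + pad).astype(int) + 1, grid.shape)
    member = np.zeros(grid.shape, dtype=bool)
    if np.all(hi > lo):
        sub = np.stack(
            np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"),
            axis=-1,
        )
        world = grid.voxel_to_world(sub.reshape(-1, 3))
        d = np.linalg.norm(world - center_mm, axis=1)
        inside = (d <= radius_mm + 1e-12).reshape(sub.shape[:3])
        member[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    if not member.any():
        warnings.warn(
            f"sphere_mask: empty mask (center {center_mm}, radius {radius_mm} mm)",
            stacklevel=2,
        )
    return Mask(grid, member)


def percentile_threshold(map: ScalarMap, roi: Mask, percent: float,
                         direction: Literal["lowest", "highest"]) -> Mask:
    """Retain the top ``percent`` of ROI voxels by lowest or highest value.

    Implements the nearest-rank rule: exactly ``ceil(percent/100 * N)`` voxels
    are kept, where ``N`` is the number of voxels in ``roi`` that carry a
    defined value. Ties at the cutoff are resolved by value and then by flat
    voxel index, giving a deterministic total order, and the retained sets are
    nested across increasing ``percent``.
    """
    if not (0 < percent <= 100):
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    if direction not in ("lowest", "highest"):
        raise ValueError(f"direction must be 'lowest' or 'highest', got {direction!r}")
    map.grid.require_same(roi.grid, "ROI")
    eligible = roi.member & map.valid.member
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("empty ROI: no defined voxels to threshold")
    # small backoff so an exactly-integral rank is not pushed up by rounding
    k = max(1, int(np.ceil(percent / 100.0 * n - 1e-9)))
    flat = np.flatnonzero(eligible.ravel())
    vals = map.value.ravel()[flat]
    key = vals if direction == "lowest" else -vals
    order = np.lexsort((flat, key))  # primary: value; secondary: voxel index
    keep = flat[order[:k]]
    member = np.zeros(map.grid.n_voxels, dtype=bool)
    member[keep] = True
    return Mask(map.grid, member.reshape(map.grid.shape))


def connected_components(mask: Mask, connectivity: Connectivity = 26) -> LabelMap:
    """Label maximal connected voxel sets under a 6/18/26 neighbourhood.

    Labels are assigned 1..K ordered by decreasing component size, with ties
    broken by the lowest flat voxel index in the component, so the labelling
    is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    raw, k = ndimage.label(mask.member, structure=_STRUCTURES[connectivity])
    if k == 0:
        return LabelMap(mask.grid, np.zeros(mask.grid.shape, dtype=np.int32))
    sizes = np.bincount(raw.ravel())[1:]  # size per raw label 1..k
    # first (lowest) flat index per raw label; raw labels from ndimage are
    # already assigned in raster order but we do not rely on that
    first = np.full(k + 1, np.iinfo(np.int64).max, dtype=np.int64)
    flat_raw = raw.ravel()
    nz = np.flatnonzero(flat_raw)
    np.minimum.at(first, flat_raw[nz], nz)
    order = np.lexsort((first[1:], -sizes))  # decreasing size, then lowest index
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, k + 1)
    return LabelMap(mask.grid, remap[raw])


def component_voxels(labels: LabelMap, label: int) -> np.ndarray:
    """Flat voxel indices of a component, sorted ascending."""
    idx = np.flatnonzero(labels.label.ravel() == label)
    if idx.size == 0:
        raise ValueError(f"label {label} not present")
    return idx


def component_centroid(labels: LabelMap, label: int,
                       grid: VolumeGrid | None = None,
                       snap_to_component: bool = False) -> TargetPoint:
    """Unweighted mean of member-voxel world coordinates.

    The centroid of a non-convex component can fall outside the component
    itself; by default no snapping is applied. With ``snap_to_component`` the
    point is moved to the nearest member voxel centre.
    """
    grid = grid or labels.grid
    ijk = np.argwhere(labels.label == label)
    if ijk.size == 0:
        raise ValueError(f"label {label} not present")
    world = grid.voxel_to_world(ijk)
    centroid = world.mean(axis=0)
    if snap_to_component:
        nearest = int(np.argmin(np.linalg.norm(world - centroid, axis=1)))
        centroid = world[nearest]
        vox = tuple(ijk[nearest])
    else:
        vox = tuple(np.round(grid.world_to_voxel(centroid)).astype(int))
    return TargetPoint(centroid, vox, {"label": int(label), "n_voxels": len(ijk)})


def boundary_voxels(mask: Mask, connectivity: Connectivity = 6) -> Mask:
    """Member voxels adjacent to a non-member voxel (or the grid edge).

    Face adjacency (connectivity 6) yields the tightest one-voxel surface
    layer; corner adjacency (26) yields a thicker shell whose inner voxels
    sit up to a voxel diagonal below the true surface.
    """
    eroded = ndimage.binary_erosion(
        mask.member, structure=_STRUCTURES[connectivity], border_value=0
    )
    return Mask(mask.grid, mask.member & ~eroded)


def distance_to_scalp(gray: Mask, head: Mask,
                      connectivity: Connectivity = 6) -> ScalarMap:
    """Shortest Euclidean distance from each gray-matter voxel to the scalp.

    The scalp surface is the exterior boundary of the head mask (head voxels
    with a non-head face neighbour by default). Distances are straight-line
    mm between voxel centres, computed by an exact nearest-neighbour query
    against the surface voxel set (valid for any affine, including oblique),
    and are defined only on ``gray``. On an analytic sphere phantom the
    result matches ``R - r`` to within one voxel edge.
    """
    gray.grid.require_same(head.grid, "head mask")
    if head.member.all():
        raise ValueError("head mask fills the entire grid: no scalp boundary exists")
    stray = gray.count and int((gray.member & ~head.member).sum())
    if stray:
        logger.warning("distance_to_scalp: %d gray voxels lie outside the head mask",
                       stray)
    surface = boundary_voxels(head, connectivity)
    if surface.is_empty():
        raise ValueError("head mask has no boundary voxels")
    tree = cKDTree(surface.world_coords())
    out = np.full(gray.grid.shape, np.nan)
    gidx = gray.indices()
    if len(gidx):
        d, _ = tree.query(gray.grid.voxel_to_world(gidx), workers=-1)
        out[tuple(gidx.T)] = d
    return ScalarMap(gray.grid, out, Mask(gray.grid, gray.member.copy()))
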