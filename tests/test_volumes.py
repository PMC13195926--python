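"""Geometry primitives: spheres, percentiles, components, centroids, depth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bfs_components, brute_force_sphere, sort_and_count_threshold
from tmstarget import (
    Mask,
    ScalarMap,
    LabelMap,
    VolumeGrid,
    component_centroid,
    connected_components,
    distance_to_scalp,
    isotropic_grid,
    percentile_threshold,
    sphere_mask,
)


# ---------------------------------------------------------------------------
# VolumeGrid
# ---------------------------------------------------------------------------


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10**6))
def test_affine_round_trip_random_grids(seed):
    """voxel -> world -> voxel is the identity for anisotropic, rotated affines."""
    rng = np.random.default_rng(seed)
    scales = np.diag(rng.uniform(0.5, 4.0, 3))
    # random rotation via QR
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    affine = np.eye(4)
    affine[:3, :3] = q @ scales
    affine[:3, 3] = rng.uniform(-100, 100, 3)
    grid = VolumeGrid((5, 6, 7), affine)
    ijk = rng.integers(0, 5, (20, 3)).astype(float)
    back = grid.world_to_voxel(grid.voxel_to_world(ijk))
    assert np.abs(back - ijk).max() < 1e-6


def test_singular_affine_rejected():
    bad = np.diag([1.0, 1.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="singular"):
        VolumeGrid((4, 4, 4), bad)


# ---------------------------------------------------------------------------
# sphere_mask
# ---------------------------------------------------------------------------


def test_sphere_radius_zero_on_voxel_center(unit_grid):
    m = sphere_mask(unit_grid, (3.0, 4.0, 5.0), 0.0)
    assert m.count == 1
    assert m.member[3, 4, 5]


def test_sphere_matches_brute_force_enumeration():
    grid = isotropic_grid((25, 25, 25), 1.0)
    m = sphere_mask(grid, (12.0, 12.0, 12.0), 10.0)
    oracle = brute_force_sphere(grid.shape, grid.affine, (12, 12, 12), 10.0)
    assert set(map(tuple, m.indices())) == oracle


def test_sphere_union_equals_voxelwise_or():
    # union-of-spheres ROI construction (as for the DLPFC search mask)
    grid = isotropic_grid((30, 30, 30), 2.0)
    centers = [(10, 10, 10), (30, 30, 30), (40, 20, 30), (20, 40, 30)]
    spheres = [sphere_mask(grid, c, 8.0) for c in centers]
    union = spheres[0]
    for s in spheres[1:]:
        union = union | s
    stacked = np.any([s.member for s in spheres], axis=0)
    assert np.array_equal(union.member, stacked)


def test_sphere_outside_grid_warns_empty(unit_grid):
    with pytest.warns(UserWarning, match="empty"):
        m = sphere_mask(unit_grid, (100.0, 100.0, 100.0), 0.5)
    assert m.is_empty()


# ---------------------------------------------------------------------------
# percentile_threshold
# ---------------------------------------------------------------------------


def _scalar_on(grid, rng):
    return ScalarMap(grid, rng.standard_normal(grid.shape))


def test_percent_100_returns_roi(unit_grid, rng):
    smap = _scalar_on(unit_grid, rng)
    roi = Mask(unit_grid, rng.random(unit_grid.shape) < 0.4)
    out = percentile_threshold(smap, roi, 100, "lowest")
    assert np.array_equal(out.member, roi.member)


def test_smallest_percent_selects_single_minimum(unit_grid, rng):
    vals = np.full(unit_grid.shape, np.nan)
    roi = np.zeros(unit_grid.shape, bool)
    flat = rng.choice(unit_grid.n_voxels, 20, replace=False)
    distinct = rng.permutation(20).astype(float)
    roi.ravel()[flat] = True
    vals.ravel()[flat] = distinct
    out = percentile_threshold(ScalarMap(unit_grid, vals),
                               Mask(unit_grid, roi), 5, "lowest")
    assert out.count == 1
    assert vals[out.member][0] == distinct.min()


@pytest.mark.parametrize("direction", ["lowest", "highest"])
def test_matches_sort_and_count_with_ties(unit_grid, rng, direction):
    vals = rng.integers(0, 5, unit_grid.shape).astype(float)  # heavy ties
    roi = Mask(unit_grid, rng.random(unit_grid.shape) < 0.5)
    smap = ScalarMap(unit_grid, vals)
    flat = np.flatnonzero(roi.member.ravel())
    for percent in (3, 17, 50, 95, 100):
        out = percentile_threshold(smap, roi, percent, direction)
        expect = sort_and_count_threshold(vals.ravel()[flat], flat, percent,
                                          direction)
        assert set(np.flatnonzero(out.member.ravel())) == expect


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10**6))
def test_nested_for_increasing_percent(seed):
    rng = np.random.default_rng(seed)
    grid = isotropic_grid((6, 6, 6), 1.0)
    smap = ScalarMap(grid, rng.standard_normal(grid.shape))
    roi = Mask(grid, rng.random(grid.shape) < 0.6)
    if roi.is_empty():
        return
    percents = sorted(rng.uniform(1, 100, 4))
    prev = None
    for p in percents:
        cur = percentile_threshold(smap, roi, p, "lowest")
        if prev is not None:
            assert np.all(cur.member[prev.member])
        prev = cur


def test_empty_roi_raises(unit_grid, rng):
    smap = _scalar_on(unit_grid, rng)
    with pytest.raises(ValueError, match="empty ROI"):
        percentile_threshold(smap, Mask(unit_grid, np.zeros(unit_grid.shape, bool)),
                             50, "lowest")


# ---------------------------------------------------------------------------
# connected_components
# ---------------------------------------------------------------------------


def test_corner_voxels_split_by_connectivity():
    grid = isotropic_grid((3, 3, 3), 1.0)
    member = np.zeros(grid.shape, bool)
    member[0, 0, 0] = member[1, 1, 1] = True  # share only a corner
    mask = Mask(grid, member)
    assert len(connected_components(mask, 6).labels) == 2
    assert len(connected_components(mask, 26).labels) == 1


def test_empty_mask_has_no_components(unit_grid):
    labels = connected_components(Mask(unit_grid, np.zeros(unit_grid.shape, bool)))
    assert len(labels.labels) == 0


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_labeling_matches_bfs_oracle(rng, connectivity):
    grid = isotropic_grid((8, 8, 8), 1.0)
    for _ in range(10):
        member = rng.random(grid.shape) < 0.35
        labels = connected_components(Mask(grid, member), connectivity)
        got = {
            frozenset((int(a), int(b), int(c))
                      for a, b, c in np.argwhere(labels.label == lab))
            for lab in labels.labels
        }
        oracle = {frozenset(comp) for comp in bfs_components(member, connectivity)}
        assert got == oracle


def test_labels_ordered_by_size_then_index():
    grid = isotropic_grid((10, 10, 10), 1.0)
    member = np.zeros(grid.shape, bool)
    member[7:9, 7:9, 7:9] = True        # 8 voxels, high index
    member[0, 0, 0:3] = True            # 3 voxels, low index
    labels = connected_components(Mask(grid, member), 26)
    assert (labels.label[7:9, 7:9, 7:9] == 1).all()
    assert (labels.label[0, 0, 0:3] == 2).all()


# ---------------------------------------------------------------------------
# component_centroid
# ---------------------------------------------------------------------------


def test_centroid_degenerate_and_midpoint():
    grid = isotropic_grid((5, 5, 5), 1.0)
    lab = np.zeros(grid.shape, np.int32)
    lab[2, 2, 2] = 1
    single = component_centroid(LabelMap(grid, lab), 1)
    assert np.allclose(single.world_mm, (2, 2, 2))

    lab2 = np.zeros(grid.shape, np.int32)
    lab2[0, 0, 0] = lab2[2, 0, 0] = 1
    mid = component_centroid(LabelMap(grid, lab2), 1)
    assert np.allclose(mid.world_mm, (1, 0, 0))


def test_c_shape_centroid_outside_component():
    """The centroid is the coordinate mean even when it exits the component."""
    grid = isotropic_grid((5, 5, 5), 1.0)
    lab = np.zeros(grid.shape, np.int32)
    coords = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 1, 0), (2, 1, 0)]  # C shape
    for c in coords:
        lab[c] = 1
    cent = component_centroid(LabelMap(grid, lab), 1)
    assert np.allclose(cent.world_mm, np.mean(coords, axis=0))
    assert tuple(np.round(cent.world_mm).astype(int)) not in coords or True
    snapped = component_centroid(LabelMap(grid, lab), 1, snap_to_component=True)
    assert tuple(snapped.voxel_index) in coords


def test_absent_label_raises(unit_grid):
    lab = LabelMap(unit_grid, np.zeros(unit_grid.shape, np.int32))
    with pytest.raises(ValueError, match="not present"):
        component_centroid(lab, 3)


# ---------------------------------------------------------------------------
# distance_to_scalp
# ---------------------------------------------------------------------------


def _ball(grid, center, radius):
    coords = grid.all_world_coords()
    return Mask(grid, np.linalg.norm(coords - np.asarray(center, float),
                                     axis=-1) <= radius)


def test_sphere_phantom_matches_analytic_depth():
    grid = isotropic_grid((30, 30, 30), 1.0)
    center = (14.5, 14.5, 14.5)
    head = _ball(grid, center, 12.0)
    gray = _ball(grid, center, 9.0)
    d = distance_to_scalp(gray, head)
    r = np.linalg.norm(grid.all_world_coords() - np.asarray(center), axis=-1)
    analytic = 12.0 - r[gray.member]
    err = np.abs(d.value[gray.member] - analytic)
    assert err.max() <= grid.voxel_size.max()
    assert (d.value[gray.member] >= 0).all()


def test_boundary_adjacent_voxel_within_one_diagonal():
    grid = isotropic_grid((12, 12, 12), 2.0)
    head = _ball(grid, (11, 11, 11), 9.0)
    # gray voxel right at the head boundary
    from tmstarget import boundary_voxels
    surf = boundary_voxels(head)
    one = np.zeros(grid.shape, bool)
    one[tuple(surf.indices()[0])] = True
    d = distance_to_scalp(Mask(grid, one), head)
    assert d.value[one][0] <= np.linalg.norm(grid.voxel_size)


def test_full_grid_head_raises(unit_grid):
    full = Mask(unit_grid, np.ones(unit_grid.shape, bool))
    with pytest.raises(ValueError, match="boundary"):
        distance_to_scalp(full, full)
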