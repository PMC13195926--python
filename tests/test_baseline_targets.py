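"""Cluster and cone baselines, LOOCV threshold tuning, surface seeding."""

import numpy as np
import pytest

from tmstarget import (
    ClusterSettings,
    ConeKernel,
    Mask,
    ScalarMap,
    SeedTimecourse,
    TargetPoint,
    ThresholdGrid,
    TimeSeriesVolume,
    cluster_target,
    cone_target,
    isotropic_grid,
    loocv_cluster_threshold,
    surface_seeds,
    tree_based_target,
)
from tmstarget import LabelMap


def _all(grid):
    return Mask(grid, np.ones(grid.shape, bool))


# ---------------------------------------------------------------------------
# cluster_target
# ---------------------------------------------------------------------------


def test_largest_component_wins():
    grid = isotropic_grid((10, 4, 4), 1.0)
    fc = np.zeros(grid.shape)
    fc[0:2, 0, 0] = -1.0           # 2-voxel component
    fc[5:9, 0:2, 0] = -0.9         # 8-voxel component, weaker but larger
    fc += np.arange(grid.n_voxels).reshape(grid.shape) * 1e-6  # break ties
    got = cluster_target(ScalarMap(grid, fc), _all(grid),
                         ClusterSettings(fc_percent=100 * 10 / grid.n_voxels))
    assert 5 <= got.world_mm[0] <= 9  # centroid of the larger component


def test_single_blob_centroid_regardless_of_depth():
    grid = isotropic_grid((7, 7, 7), 1.0)
    fc = np.zeros(grid.shape)
    fc[2:5, 2:5, 2:5] = -1.0
    fc += np.random.default_rng(0).random(grid.shape) * 1e-9
    got = cluster_target(ScalarMap(grid, fc), _all(grid),
                         ClusterSettings(fc_percent=100 * 27 / grid.n_voxels))
    assert np.allclose(got.world_mm, (3, 3, 3), atol=1e-6)


def test_equal_size_components_tie_stable():
    grid = isotropic_grid((10, 3, 3), 1.0)
    fc = np.zeros(grid.shape)
    fc[0:3, 0, 0] = -1.0
    fc[6:9, 0, 0] = -1.0
    smap = ScalarMap(grid, fc)
    s = ClusterSettings(fc_percent=100 * 6 / grid.n_voxels)
    runs = {tuple(cluster_target(smap, _all(grid), s).world_mm)
            for _ in range(3)}
    assert len(runs) == 1
    # ordered tie-break: lowest voxel index component carries label 1
    assert next(iter(runs))[0] == pytest.approx(1.0)


def test_absolute_threshold_dialect():
    grid = isotropic_grid((5, 5, 5), 1.0)
    fc = np.zeros(grid.shape)
    fc[1:3, 1, 1] = -0.8
    got = cluster_target(ScalarMap(grid, fc), _all(grid),
                         ClusterSettings(absolute_r=-0.5))
    assert np.allclose(got.world_mm, (1.5, 1, 1))


# ---------------------------------------------------------------------------
# LOOCV threshold selection
# ---------------------------------------------------------------------------


def _loocv_subject(rng, blob_width, T=60):
    """A 1D subject whose best cluster threshold depends on blob width."""
    grid = isotropic_grid((20, 1, 1), 1.0)
    seed = rng.standard_normal(T)
    coupling = np.zeros(20)
    lo, hi = 10 - blob_width // 2, 10 + (blob_width + 1) // 2
    coupling[lo:hi] = -0.9
    series = coupling[:, None, None, None] * seed \
        + 0.05 * rng.standard_normal((20, 1, 1, T))
    ts = TimeSeriesVolume(grid, series)
    fc_vals = coupling + rng.normal(0, 1e-3, 20)
    fc = ScalarMap(grid, fc_vals.reshape(20, 1, 1))
    return (fc, ts, SeedTimecourse(seed), _all(grid))


def test_identical_subjects_get_identical_threshold(rng):
    subj = _loocv_subject(np.random.default_rng(0), blob_width=6)
    out = loocv_cluster_threshold([subj, subj, subj], [10, 30, 50])
    assert len(set(out)) == 1


def test_chosen_thresholds_are_members_of_candidates(rng):
    subjects = [_loocv_subject(np.random.default_rng(k), blob_width=4 + 2 * k)
                for k in range(3)]
    out = loocv_cluster_threshold(subjects, [10, 25, 60])
    assert all(t in (10, 25, 60) for t in out)


def test_held_out_threshold_determined_by_training_pair():
    """Held-out subject 0's threshold reflects only subjects 1 and 2."""
    grid = isotropic_grid((10, 1, 1), 1.0)
    T = 30
    seed = np.sin(np.arange(T))

    def subject(best_cells):
        # evaluation FC is favourable only when the cluster centroid lands on
        # best_cells; engineer fc so different percents select different cells
        fc = np.linspace(-1.0, -0.1, 10)
        series = np.zeros((10, 1, 1, T))
        for i in range(10):
            series[i, 0, 0] = (-seed if i in best_cells else
                               0.01 * np.cos(np.arange(T) * (i + 2)))
        return (ScalarMap(grid, fc.reshape(10, 1, 1)),
                TimeSeriesVolume(grid, series), SeedTimecourse(seed),
                _all(grid))

    # percent 10 -> single most-negative voxel {0}; percent 50 -> voxels 0-4
    s1 = subject({0})        # favours stringent threshold
    s2 = subject({0})
    s3 = subject({0, 1, 2})  # indifferent-ish
    out = loocv_cluster_threshold([s3, s1, s2], [10, 50], eval_radius_mm=0.0)
    assert out[0] == 10  # decided by s1, s2 alone


def test_fewer_than_two_subjects_rejected(rng):
    with pytest.raises(ValueError, match="2 subjects"):
        loocv_cluster_threshold([_loocv_subject(rng, 4)], [10])


# ---------------------------------------------------------------------------
# surface_seeds
# ---------------------------------------------------------------------------


def test_slab_thinning_respects_spacing():
    grid = isotropic_grid((12, 12, 3), 1.0)
    brain = np.zeros(grid.shape, bool)
    brain[:, :, 1] = True  # 1-voxel-thick slab: everything is surface
    mask = Mask(grid, brain.copy())
    seeds = surface_seeds(mask, Mask(grid, brain), 4.0)
    pts = np.array([s.world_mm for s in seeds])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 4.0
    assert len(seeds) >= 9  # ~4 mm lattice over a 12x12 sheet


def test_spacing_zero_keeps_all_surface_voxels():
    grid = isotropic_grid((6, 6, 6), 1.0)
    brain = np.zeros(grid.shape, bool)
    brain[1:5, 1:5, 1:5] = True
    seeds = surface_seeds(Mask(grid, brain.copy()), Mask(grid, brain), 0.0)
    interior = np.zeros(grid.shape, bool)
    interior[2:4, 2:4, 2:4] = True
    assert len(seeds) == brain.sum() - interior.sum()


def test_interior_only_mask_is_empty_with_warning(caplog):
    grid = isotropic_grid((8, 8, 8), 1.0)
    brain = np.zeros(grid.shape, bool)
    brain[1:7, 1:7, 1:7] = True
    interior = np.zeros(grid.shape, bool)
    interior[3:5, 3:5, 3:5] = True
    with caplog.at_level("WARNING", logger="tmstarget"):
        seeds = surface_seeds(Mask(grid, interior), Mask(grid, brain), 4.0)
    assert seeds == []
    assert "no brain-surface voxels" in caplog.text


# ---------------------------------------------------------------------------
# ConeKernel and cone_target
# ---------------------------------------------------------------------------


def test_kernel_mean_one_on_any_resolution(rng):
    kernel = ConeKernel()
    for vox in (0.7, 1.0, 2.3):
        grid = isotropic_grid((31, 31, 31), vox)
        center = np.array(grid.shape) * vox / 2
        world = grid.all_world_coords()
        d = np.linalg.norm(world - center, axis=-1)
        inside = d <= kernel.outer_radius
        w = kernel.realized_weights(d[inside])
        assert w.mean() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()
        # non-increasing with distance
        order = np.argsort(d[inside])
        assert (np.diff(w[order]) <= 1e-12).all()


def test_constant_field_ties_to_first_seed():
    grid = isotropic_grid((10, 10, 10), 2.0)
    fc = ScalarMap(grid, np.full(grid.shape, 0.37))
    seeds = [TargetPoint((4.0, 4.0, 4.0), (2, 2, 2)),
             TargetPoint((14.0, 14.0, 14.0), (7, 7, 7))]
    got = cone_target(fc, seeds)
    assert np.array_equal(got.world_mm, seeds[0].world_mm)
    assert got.meta["cone_score"] == pytest.approx(0.37)


def test_dominant_minimum_wins():
    grid = isotropic_grid((20, 20, 20), 2.0)
    world = grid.all_world_coords()
    blob = np.exp(-np.linalg.norm(world - np.array([10, 10, 10.0]), axis=-1) ** 2
                  / (2 * 15.0 ** 2))
    fc = ScalarMap(grid, -blob)
    seeds = [TargetPoint((10.0, 10.0, 10.0), (5, 5, 5)),
             TargetPoint((30.0, 30.0, 30.0), (15, 15, 15))]
    got = cone_target(fc, seeds)
    assert np.array_equal(got.world_mm, seeds[0].world_mm)


def test_toy_sphere_weighted_mean_by_hand():
    """Five voxels at listed distances: score equals the arithmetic oracle."""
    grid = isotropic_grid((9, 1, 1), 3.0)  # voxels at x = 0,3,6,...,24
    fc_vals = np.array([-1.0, -0.5, 0.2, 0.4, 0.8, 0.0, 0.0, 0.0, 0.0])
    valid = np.zeros(grid.shape, bool)
    valid[:5, 0, 0] = True
    fc = ScalarMap(grid, fc_vals.reshape(9, 1, 1),
                   Mask(grid, valid))
    kernel = ConeKernel()
    seed = TargetPoint((0.0, 0.0, 0.0), (0, 0, 0))
    got = cone_target(fc, [seed], kernel)
    d = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
    w = np.maximum(0, 1 - d / 12.0)
    w = w / w.mean()
    expect = (w @ fc_vals[:5]) / w.sum()
    assert got.meta["cone_score"] == pytest.approx(expect)


def test_all_seeds_out_of_reach_raise(caplog):
    grid = isotropic_grid((5, 5, 5), 1.0)
    fc = ScalarMap(grid, np.full(grid.shape, np.nan))  # nothing defined
    seed = TargetPoint((2.0, 2.0, 2.0), (2, 2, 2))
    with pytest.raises(ValueError):
        cone_target(fc, [seed])


# ---------------------------------------------------------------------------
# collapse test: cluster == tree in the degenerate single-component case
# ---------------------------------------------------------------------------


def test_tree_collapses_to_cluster_for_single_component():
    grid = isotropic_grid((8, 8, 8), 1.0)
    rng = np.random.default_rng(5)
    fc_vals = rng.standard_normal(grid.shape)
    fc_vals[2:6, 2:6, 2:6] -= 10.0  # one dominant block; always one component
    fc = ScalarMap(grid, fc_vals)
    depth = ScalarMap(grid, np.zeros(grid.shape))
    parc = LabelMap(grid, np.ones(grid.shape, np.int32))
    mask = Mask(grid, np.ones(grid.shape, bool))
    spec = ThresholdGrid(depth_percents=(100,), fc_percents=(10,))
    tree_t, forest = tree_based_target(parc, fc, depth, mask, {1}, spec)
    clus_t = cluster_target(fc, mask, ClusterSettings(fc_percent=10))
    assert len(forest.candidates) == 1
    assert np.allclose(tree_t.world_mm, clus_t.world_mm)
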