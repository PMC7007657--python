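import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dirqa.geometry_metrics import (
    EmptyMaskError,
    GridMismatchError,
    MetricUndefinedError,
    check_topology,
    compare_structures,
    dice,
    extract_surface,
    hausdorff_distance,
    mean_surface_distance,
    surface_distances,
    volume,
)
from dirqa.io_formats import StructureMask, VoxelGrid
from dirqa.synthetic_cohort import sphere_mask, torus_mask

from conftest import concentric_sphere_pair, random_mask_pair


def _mask(occ, spacing=(1.0, 1.0, 1.0)):
    return StructureMask(grid=VoxelGrid(occ.shape, spacing), occupancy=occ, label="x")


def _block(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    occ = np.zeros(shape, dtype=bool)
    occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return _mask(occ, spacing)


# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_surface(occ):
    """O(n) neighbour scan: occupied voxel with a face-adjacent background or
    out-of-bounds neighbour."""
    out = []
    for idx in np.argwhere(occ):
        i, j, k = idx
        on_surface = False
        for d in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]:
            n = (i + d[0], j + d[1], k + d[2])
            if any(c < 0 or c >= s for c, s in zip(n, occ.shape)) or not occ[n]:
                on_surface = True
                break
        if on_surface:
            out.append((i, j, k))
    return np.array(sorted(out))


def brute_directed_distances(test_occ, ref_occ, spacing):
    """All-pairs minimum distance from each test surface voxel centre to the
    nearest reference surface voxel centre."""
    sp = np.asarray(spacing)
    t = brute_surface(test_occ) * sp
    r = brute_surface(ref_occ) * sp
    return np.array([np.min(np.linalg.norm(r - p, axis=1)) for p in t])


# ---------------------------------------------------------------------------


class TestVolume:
    def test_unit_block(self):
        assert volume(_block((12, 12, 12), (1, 1, 1), (11, 11, 11))) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self):
        assert volume(_mask(np.zeros((5, 5, 5), dtype=bool))) == 0.0

    def test_sphere_against_analytic_volume(self):
        m = sphere_mask(20.0, spacing=(0.5, 0.5, 0.5))
        assert volume(m) == pytest.approx(4 / 3 * np.pi * 20**3 / 1000, rel=0.01)


class TestSurfaceExtraction:
    @pytest.mark.parametrize(
        "shape,expected",
        [((3, 3, 3), 26), ((5, 5, 5), 98), ((1, 1, 1), 1)],
    )
    def test_solid_cube_surface_counts(self, shape, expected):
        m = _mask(np.ones(shape, dtype=bool))
        assert len(extract_surface(m)) == expected

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, _ = random_mask_pair(rng)
            got = np.array(sorted(map(tuple, extract_surface(a))))
            np.testing.assert_array_equal(got, brute_surface(a.occupancy))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_surface(_mask(np.zeros((3, 3, 3), dtype=bool)))


class TestDice:
    def test_identical_disjoint_and_undefined(self):
        a = _block((10, 10, 10), (1, 1, 1), (5, 5, 5))
        b = _block((10, 10, 10), (6, 6, 6), (9, 9, 9))
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0
        empty = _mask(np.zeros((10, 10, 10), dtype=bool))
        with pytest.raises(MetricUndefinedError):
            dice(empty, empty)

    def test_concentric_spheres_analytic(self):
        inner, outer = concentric_sphere_pair(20.0, 25.0)
        assert dice(inner, outer) == pytest.approx(2 * 20**3 / (20**3 + 25**3), abs=0.01)

    def test_grid_mismatch_rejected(self):
        a = _block((10, 10, 10), (1, 1, 1), (5, 5, 5))
        b = _block((10, 10, 10), (1, 1, 1), (5, 5, 5), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(GridMismatchError):
            dice(a, b)


class TestSurfaceDistances:
    def test_identical_masks_all_zero(self):
        a = _block((10, 10, 10), (2, 2, 2), (8, 8, 8))
        assert np.all(surface_distances(a, a).distances == 0)

    def test_concentric_spheres_near_constant(self):
        inner, outer = concentric_sphere_pair(20.0, 25.0)
        d = surface_distances(inner, outer).distances
        diag = np.sqrt(3)
        assert np.all(np.abs(d - 5.0) <= diag)

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.7, 1.1, 2.3)])
    def test_matches_brute_force_all_pairs(self, spacing):
        rng = np.random.default_rng(11)
        for _ in range(15):
            a, b = random_mask_pair(rng, spacing=spacing)
            got = np.sort(surface_distances(a, b).distances)
            exp = np.sort(brute_directed_distances(a.occupancy, b.occupancy, spacing))
            np.testing.assert_allclose(got, exp, atol=1e-9)

    def test_empty_input_raises(self):
        a = _block((5, 5, 5), (1, 1, 1), (4, 4, 4))
        empty = _mask(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(EmptyMaskError):
            surface_distances(a, empty)


class TestAggregateMetrics:
    def test_identical_masks_zero_distance(self):
        a = _block((10, 10, 10), (2, 2, 2), (8, 8, 8))
        assert mean_surface_distance(a, a) == 0.0
        assert mean_surface_distance(a, a, mode="directed") == 0.0
        assert hausdorff_distance(a, a) == 0.0

    def test_concentric_spheres_msd_hd(self):
        inner, outer = concentric_sphere_pair(20.0, 25.0)
        diag = np.sqrt(3)
        for mode in ("symmetric", "directed"):
            assert mean_surface_distance(inner, outer, mode=mode) == pytest.approx(5.0, abs=diag)
        assert hausdorff_distance(inner, outer) == pytest.approx(5.0, abs=diag)

    def test_equals_brute_force_per_mode(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a, b = random_mask_pair(rng)
            d_ab = brute_directed_distances(a.occupancy, b.occupancy, a.grid.spacing)
            d_ba = brute_directed_distances(b.occupancy, a.occupancy, a.grid.spacing)
            assert mean_surface_distance(a, b, mode="directed") == pytest.approx(d_ab.mean(), abs=1e-9)
            assert mean_surface_distance(a, b) == pytest.approx(np.concatenate([d_ab, d_ba]).mean(), abs=1e-9)
            assert hausdorff_distance(a, b) == pytest.approx(max(d_ab.max(), d_ba.max()), abs=1e-9)

    def test_symmetry_translation_and_spacing_scaling(self):
        rng = np.random.default_rng(5)
        a, b = random_mask_pair(rng, shape=(10, 10, 10))
        # symmetry
        assert dice(a, b) == dice(b, a)
        assert mean_surface_distance(a, b) == pytest.approx(mean_surface_distance(b, a))
        assert hausdorff_distance(a, b) == pytest.approx(hausdorff_distance(b, a))
        # whole-voxel translation of both masks
        shift = (2, 1, 3)
        big = np.zeros((16, 16, 16), dtype=bool)
        occ_a = np.zeros_like(big)
        occ_b = np.zeros_like(big)
        occ_a[: a.occupancy.shape[0], : a.occupancy.shape[1], : a.occupancy.shape[2]] = a.occupancy
        occ_b[: b.occupancy.shape[0], : b.occupancy.shape[1], : b.occupancy.shape[2]] = b.occupancy
        ta = _mask(np.roll(occ_a, shift, axis=(0, 1, 2)))
        tb = _mask(np.roll(occ_b, shift, axis=(0, 1, 2)))
        ua, ub = _mask(occ_a), _mask(occ_b)
        assert dice(ta, tb) == dice(ua, ub)
        assert mean_surface_distance(ta, tb) == pytest.approx(mean_surface_distance(ua, ub))
        # spacing scaling by k scales distances, leaves dice unchanged
        k = 2.5
        sa = StructureMask(grid=VoxelGrid(a.occupancy.shape, tuple(k * s for s in a.grid.spacing)), occupancy=a.occupancy)
        sb = StructureMask(grid=sa.grid, occupancy=b.occupancy)
        assert dice(sa, sb) == dice(a, b)
        assert mean_surface_distance(sa, sb) == pytest.approx(k * mean_surface_distance(a, b))
        assert hausdorff_distance(sa, sb) == pytest.approx(k * hausdorff_distance(a, b))

    def test_msd_bounded_by_hd(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, b = random_mask_pair(rng)
            assert mean_surface_distance(a, b) <= hausdorff_distance(a, b) + 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_metric_bounds_on_random_pairs(self, seed):
        """0 <= dice <= 1 and 0 <= msd <= hd <= grid diagonal for any pair."""
        a, b = random_mask_pair(np.random.default_rng(seed), shape=(7, 7, 7))
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        msd = mean_surface_distance(a, b)
        hd = hausdorff_distance(a, b)
        diag = np.linalg.norm(np.array(a.grid.shape) * np.array(a.grid.spacing))
        assert 0.0 <= msd <= hd <= diag


class TestTopology:
    def test_solid_sphere(self):
        rep = check_topology(sphere_mask(8.0))
        assert rep.n_components == 1 and not rep.has_handle

    def test_torus_has_handle(self):
        rep = check_topology(torus_mask())
        assert rep.has_handle and rep.euler_characteristic == 0

    def test_two_disjoint_spheres(self):
        s = sphere_mask(4.0, pad_mm=2.0)
        occ = np.zeros((s.occupancy.shape[0] * 2 + 4,) + s.occupancy.shape[1:], dtype=bool)
        occ[: s.occupancy.shape[0]] = s.occupancy
        occ[s.occupancy.shape[0] + 4 :] = s.occupancy
        assert check_topology(_mask(occ)).n_components == 2

    def test_metrics_complete_on_exotic_topologies(self):
        t = torus_mask()
        s = StructureMask(grid=t.grid, occupancy=np.roll(t.occupancy, 2, axis=0), label="x")
        rec = compare_structures(t, s)
        assert rec.status == "ok" and 0 <= rec.dsc <= 1 and rec.msd <= rec.hd


class TestCompareStructures:
    def test_identical_masks(self):
        a = _block((10, 10, 10), (2, 2, 2), (8, 8, 8))
        rec = compare_structures(a, a)
        assert (rec.dsc, rec.msd, rec.hd) == (1.0, 0.0, 0.0)

    def test_concentric_spheres(self):
        inner, outer = concentric_sphere_pair(20.0, 25.0)
        rec = compare_structures(inner, outer)
        assert rec.dsc == pytest.approx(0.677, abs=0.01)
        assert rec.msd == pytest.approx(5.0, abs=np.sqrt(3))
        assert rec.hd == pytest.approx(5.0, abs=np.sqrt(3))
        assert rec.msd <= rec.hd

    def test_empty_pairs_flagged_not_raised(self):
        empty = _mask(np.zeros((6, 6, 6), dtype=bool))
        full = _block((6, 6, 6), (1, 1, 1), (4, 4, 4))
        assert compare_structures(empty, empty).status == "failed_both_empty"
        rec = compare_structures(empty, full)
        assert rec.status == "failed_empty_test" and rec.dsc == 0.0
        assert compare_structures(full, empty).status == "failed_empty_ref"
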