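import dataclasses

import numpy as np
import pandas as pd
import pytest

from dirqa.geometry_metrics import (
    check_topology,
    hausdorff_distance,
    mean_surface_distance,
    volume,
)
from dirqa.io_formats import StructureMask, VoxelGrid, load_manifest, read_mask
from dirqa.synthetic_cohort import (
    CohortConfig,
    DeformationSpec,
    GridSpec,
    OrganSpec,
    make_organ_phantom,
    perturb_contour,
    random_displacement_field,
    simulate_cohort,
    sphere_mask,
    warp_mask,
)


class TestPhantoms:
    def test_zero_variability_reproducible_across_draws(self):
        spec = {"prostate": OrganSpec("ellipsoid", (30, 30, 30), (10, 12, 14), 0.0, 0.0, 0.0, 0.0)}
        grid = VoxelGrid((60, 60, 60), (1.0, 1.0, 1.0))
        m1 = make_organ_phantom(spec, grid, rng=np.random.default_rng(1))["prostate"]
        m2 = make_organ_phantom(spec, grid, rng=np.random.default_rng(999))["prostate"]
        np.testing.assert_array_equal(m1.occupancy, m2.occupancy)

    def test_prostate_ellipsoid_volume_analytic(self):
        spec = {"prostate": OrganSpec("ellipsoid", (35, 35, 35), (20, 22, 25), 0.0, 0.0, 0.0, 0.0)}
        grid = VoxelGrid((72, 72, 72), (1.0, 1.0, 1.0))
        m = make_organ_phantom(spec, grid)["prostate"]
        expected = 4 / 3 * np.pi * 20 * 22 * 25 / 1000  # ~46.1 cm^3
        assert volume(m) == pytest.approx(expected, rel=0.02)

    def test_pinhole_bladder_is_genus_one(self):
        spec = {"bladder": OrganSpec("sphere", (30, 30, 30), (18,), 0.0, 0.0, 0.0, 0.0)}
        grid = VoxelGrid((60, 60, 60), (1.0, 1.0, 1.0))
        m = make_organ_phantom(spec, grid, pinhole=True, pinhole_radius=4.0)["bladder"]
        assert check_topology(m).has_handle

    def test_structure_exceeding_grid_raises(self):
        spec = {"bladder": OrganSpec("sphere", (30, 30, 30), (40,), 0.0, 0.0, 0.0, 0.0)}
        grid = VoxelGrid((60, 60, 60), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="exceeds the grid"):
            make_organ_phantom(spec, grid)


class TestDisplacementField:
    grid = VoxelGrid((64, 64, 64), (1.0, 1.0, 1.0))

    def test_zero_amplitude_is_zero_field(self):
        f = random_displacement_field(DeformationSpec(0.0, 20.0), self.grid, np.random.default_rng(0))
        assert np.all(f == 0)

    def test_fixed_seed_bit_identical(self):
        f1 = random_displacement_field(DeformationSpec(3.0, 20.0), self.grid, np.random.default_rng(5))
        f2 = random_displacement_field(DeformationSpec(3.0, 20.0), self.grid, np.random.default_rng(5))
        np.testing.assert_array_equal(f1, f2)

    def test_empirical_sd_matches_amplitude(self):
        f = random_displacement_field(DeformationSpec(3.0, 20.0), self.grid, np.random.default_rng(2))
        for c in range(3):
            assert f[c].std() == pytest.approx(3.0, rel=0.10)

    def test_smoothness_scale(self):
        # neighbouring voxels should be strongly correlated at 20 mm correlation length
        f = random_displacement_field(DeformationSpec(3.0, 20.0), self.grid, np.random.default_rng(3))
        diffs = np.diff(f[0], axis=0)
        assert np.abs(diffs).mean() < 0.5  # much smaller than the 3 mm amplitude


class TestWarp:
    def _ball(self):
        return sphere_mask(8.0, pad_mm=8.0)

    def test_zero_field_identity(self):
        m = self._ball()
        w = warp_mask(m, np.zeros((3,) + m.grid.shape))
        np.testing.assert_array_equal(w.occupancy, m.occupancy)

    def test_whole_voxel_translation_exact(self):
        m = self._ball()
        field = np.zeros((3,) + m.grid.shape)
        field[0] += 3.0  # +3 voxels along axis 0 at 1 mm spacing
        w = warp_mask(m, field)
        np.testing.assert_array_equal(w.occupancy, np.roll(m.occupancy, 3, axis=0))

    def test_hausdorff_bounded_by_max_displacement(self):
        m = self._ball()
        rng = np.random.default_rng(4)
        field = random_displacement_field(DeformationSpec(2.0, 15.0), m.grid, rng)
        w = warp_mask(m, field)
        bound = np.abs(field).max() * np.sqrt(3) + np.linalg.norm(m.grid.spacing)
        assert hausdorff_distance(w, m) <= bound


class TestPerturbContour:
    def test_sigma_zero_identity(self):
        m = sphere_mask(10.0)
        w = perturb_contour(m, 0.0, 1)
        np.testing.assert_array_equal(w.occupancy, m.occupancy)

    def test_fixed_seed_reproducible(self):
        m = sphere_mask(10.0)
        w1 = perturb_contour(m, 1.5, 42)
        w2 = perturb_contour(m, 1.5, 42)
        np.testing.assert_array_equal(w1.occupancy, w2.occupancy)

    def test_msd_grows_with_sigma(self):
        m = sphere_mask(15.0, spacing=(1.0, 1.0, 1.0), pad_mm=8.0)
        msd = {}
        for sigma in (1.0, 2.0):
            vals = [mean_surface_distance(perturb_contour(m, sigma, seed), m) for seed in range(8)]
            msd[sigma] = np.mean(vals)
        assert msd[2.0] > msd[1.0]


def _tiny_config(seed=0, **kw):
    kw.setdefault("n_patients", 2)
    kw.setdefault("n_pinhole_patients", 1)
    return CohortConfig.reduced(master_seed=seed, **kw)


class TestSimulateCohort:
    def test_manifest_design_counts(self):
        cohort = simulate_cohort(_tiny_config())
        df = cohort.manifest.records
        counts = df["role"].value_counts().to_dict()
        n, s = 2, 8
        assert counts["ground_truth"] == n * 5 * s
        assert counts["propagated_CT_MR"] == n * 4 * s
        assert counts["propagated_MR_MR"] == n * 3 * s
        assert counts["redelineation_IOV"] == n * s
        assert cohort.manifest.validate() == []

    def test_master_seed_determinism(self):
        c1 = simulate_cohort(_tiny_config(seed=3))
        c2 = simulate_cohort(_tiny_config(seed=3))
        pd.testing.assert_frame_equal(c1.manifest.records, c2.manifest.records)
        for key in list(c1.masks)[:: max(1, len(c1.masks) // 20)]:
            np.testing.assert_array_equal(c1.masks[key].occupancy, c2.masks[key].occupancy)

    def test_different_seeds_differ(self):
        c1 = simulate_cohort(_tiny_config(seed=3))
        c2 = simulate_cohort(_tiny_config(seed=4))
        key = ("P01", "MR10", "prostate", "propagated_CT_MR")
        assert not np.array_equal(c1.masks[key].occupancy, c2.masks[key].occupancy)

    def test_ct_prostate_systematically_larger_than_mr(self):
        cohort = simulate_cohort(_tiny_config(seed=5, n_patients=4))
        for p in range(1, 5):
            v_ct = volume(cohort.mask(f"P{p:02d}", "pCT", "prostate", "ground_truth"))
            v_mr = volume(cohort.mask(f"P{p:02d}", "pMR", "prostate", "ground_truth"))
            assert v_ct > v_mr

    def test_pinhole_patient_bladder_topology(self):
        cohort = simulate_cohort(_tiny_config(seed=6))
        assert check_topology(cohort.mask("P01", "pMR", "bladder", "ground_truth")).has_handle
        assert not check_topology(cohort.mask("P02", "pMR", "bladder", "ground_truth")).has_handle

    def test_ct_surrogate_grid_has_thick_slices(self):
        cohort = simulate_cohort(_tiny_config(seed=7, n_patients=1))
        ct = cohort.mask("P01", "pCT", "prostate", "ground_truth")
        mr = cohort.mask("P01", "pMR", "prostate", "ground_truth")
        assert ct.grid.spacing[ct.grid.axis_of("CC")] == 3.0
        assert mr.grid.spacing == (2.0, 2.0, 2.5)

    def test_write_to_disk_and_reload(self, tmp_path):
        cfg = _tiny_config(seed=8, n_patients=1)
        cohort = simulate_cohort(cfg, out_dir=tmp_path)
        man = load_manifest(tmp_path / "manifest.csv")
        assert len(man) == len(cohort.manifest)
        row = man.select(role="ground_truth", scan_id="pMR", structure="prostate").iloc[0]
        m = read_mask(tmp_path / row["path"], label="prostate")
        assert not m.is_empty

    def test_invalid_config_rejected_before_output(self, tmp_path):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            CohortConfig(n_patients=2, n_pinhole_patients=5)
        with pytest.raises(ValueError):
            CohortConfig(arm_amplitudes={"CT_MR": -1.0, "MR_MR": 1.0, "IOV": 0.8})


class TestCohortStatisticalStructure:
    """Properties of the default-design cohort (shared session run)."""

    def test_arm_ordering_in_population_medians(self, default_reduced_run):
        from dirqa.cohort_stats import patient_scan_average, population_median_table

        table = population_median_table(patient_scan_average(default_reduced_run["ev"]["records"]))
        for s in default_reduced_run["config"].structures:
            assert table.loc[s, ("dsc", "MR_MR")] > table.loc[s, ("dsc", "CT_MR")]
            assert table.loc[s, ("msd", "MR_MR")] < table.loc[s, ("msd", "CT_MR")]

    def test_scan_counts_per_arm(self, default_reduced_run):
        from dirqa.cohort_stats import patient_scan_average

        summ = patient_scan_average(default_reduced_run["ev"]["records"])
        assert summ[summ["arm"] == "CT_MR"]["n_scans"].max() <= 4
        assert summ[summ["arm"] == "MR_MR"]["n_scans"].max() <= 3
        assert summ[summ["arm"] == "IOV"]["n_scans"].max() <= 1

    def test_bladder_volume_ratio_degrades_accuracy(self, default_reduced_run):
        from dirqa.cohort_stats import volume_ratio_table

        ev = default_reduced_run["ev"]
        vr = volume_ratio_table(ev["records"], ev["gt_volumes"])
        bl = vr[(vr["structure"] == "bladder") & (vr["status"] == "ok")]
        in_band = bl[(bl["ratio"] >= 0.8) & (bl["ratio"] <= 1.2)]
        out_band = bl[(bl["ratio"] < 0.8) | (bl["ratio"] > 1.2)]
        assert len(in_band) > 0 and len(out_band) > 0
        assert in_band["dsc"].mean() > out_band["dsc"].mean()
        # parabola-like trend: quadratic fit on the log-ratio scale (where a
        # ratio effect is symmetric) peaks near ratio 1 with negative curvature
        coef = np.polyfit(np.log(bl["ratio"]), bl["dsc"], 2)
        assert coef[0] < 0
        vertex = float(np.exp(-coef[1] / (2 * coef[0])))
        assert 0.9 <= vertex <= 1.1

    def test_planning_volume_bias_direction(self, default_reduced_run):
        from dirqa.cohort_stats import planning_volume_comparison

        out = planning_volume_comparison(default_reduced_run["ev"]["gt_volumes"])
        row = out[out["structure"] == "prostate"].iloc[0]
        assert row["median_pCT"] > row["median_pMR"]
        assert row["p_value"] < 0.05
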