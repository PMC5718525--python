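"""Gamma index, DVH/DDDVH/D4 statistics, profiles and contours."""

import numpy as np
import pytest

import gammagel.compare as cmp
from gammagel.compare import GammaParams, gamma_index
from gammagel.geometry import DoseGrid, GridGeometry

GEOM = GridGeometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (15, 15, 15))


def grid(data):
    return DoseGrid(np.broadcast_to(np.asarray(data, float), GEOM.shape).copy(), GEOM)


def smooth_pair(seed=0, amp=10.0, shift=0.15):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.standard_normal(GEOM.shape), 3.0)
    raw = amp * (raw - raw.min()) / np.ptp(raw)
    pert = shift * ndimage.gaussian_filter(rng.standard_normal(GEOM.shape), 2.0)
    return DoseGrid(raw, GEOM), DoseGrid(raw + pert, GEOM)


class TestDoseDifference:
    def test_identical_is_zero(self):
        g = grid(5.0)
        np.testing.assert_array_equal(cmp.dose_difference(g, g).data, 0.0)

    def test_uniform_offset(self):
        a, b = grid(5.0), grid(5.5)
        np.testing.assert_allclose(cmp.dose_difference(b, a).data, 0.5)

    def test_antisymmetry(self):
        a, b = smooth_pair(1)
        np.testing.assert_array_equal(
            cmp.dose_difference(a, b).data, -cmp.dose_difference(b, a).data
        )

    def test_geometry_mismatch_rejected(self):
        other = DoseGrid(np.zeros((5, 5, 5)), GridGeometry((0, 0, 0), (2, 2, 2), (5, 5, 5)))
        with pytest.raises(ValueError, match="common geometry"):
            cmp.dose_difference(grid(1.0), other)


class TestGammaIndex:
    def test_identical_grids_gamma_zero(self):
        g = grid(8.0)
        gm = gamma_index(g, g, GammaParams(3.0, 2.0, 10.0))
        np.testing.assert_allclose(gm.gamma, 0.0, atol=1e-12)
        assert gm.pass_rate == 100.0

    def test_flat_field_offset_by_exact_tolerance(self):
        # in a zero-gradient field DTA cannot help: gamma = dose term = 1
        calc = grid(8.0)
        meas = grid(8.0 + 0.03 * 10.0)
        gm = gamma_index(calc, meas, GammaParams(3.0, 2.0, 10.0))
        np.testing.assert_allclose(gm.gamma, 1.0, rtol=1e-9)

    def test_gamma_scales_with_dose_tol_in_flat_field(self):
        calc, meas = grid(8.0), grid(8.3)
        g1 = gamma_index(calc, meas, GammaParams(3.0, 2.0, 10.0)).gamma
        g2 = gamma_index(calc, meas, GammaParams(1.5, 2.0, 10.0)).gamma
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-9)

    def test_loosening_tolerance_never_decreases_pass(self):
        calc, meas = smooth_pair(7, shift=0.6)
        loose = gamma_index(calc, meas, GammaParams(3.0, 2.0, 10.0))
        tight = gamma_index(calc, meas, GammaParams(1.0, 1.0, 10.0))
        passed_tight = tight.gamma[np.isfinite(tight.gamma)] <= 1.0
        passed_loose = loose.gamma[np.isfinite(loose.gamma)] <= 1.0
        assert np.all(passed_loose[passed_tight])
        assert loose.pass_rate >= tight.pass_rate

    def test_low_dose_cutoff_restricts_evaluated_set(self):
        calc, meas = smooth_pair(3)
        full = gamma_index(calc, meas, GammaParams(2.0, 2.0, 10.0))
        cut = gamma_index(calc, meas, GammaParams(2.0, 2.0, 10.0, low_dose_cutoff=20.0))
        assert cut.evaluated_count < full.evaluated_count
        assert np.isnan(cut.gamma[calc.data < 2.0]).all()

    def test_empty_evaluated_set_is_error(self):
        empty = DoseGrid(np.full(GEOM.shape, np.nan), GEOM)
        with pytest.raises(ValueError, match="no voxels"):
            gamma_index(grid(1.0), empty, GammaParams(3.0, 2.0, 10.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GammaParams(0.0, 2.0, 10.0)
        with pytest.raises(ValueError):
            GammaParams(3.0, 2.0, 10.0, search_radius=1.0)
        with pytest.raises(ValueError):
            GammaParams(3.0, 2.0, 10.0, interp_step=1.0)

    def test_saturated_voxels_capped_at_boundary(self):
        calc = grid(1.0)
        meas = grid(9.0)  # 80% of norm off: far beyond the search sphere
        params = GammaParams(1.0, 1.0, 10.0, search_radius=2.0)
        gm = gamma_index(calc, meas, params)
        np.testing.assert_allclose(gm.gamma, 2.0)  # boundary = radius/dta
        assert gm.saturated.all()


class TestPassRateTable:
    def test_identical_grids_all_100(self):
        g = smooth_pair(2)[0]
        table = cmp.pass_rate_table(g, g, [(3, 2), (2, 2), (1, 1), (0.5, 0.5)])
        assert (table["pass_rate_pct"] == 100.0).all()

    def test_nested_criteria_ordering(self):
        calc, meas = smooth_pair(11, shift=0.5)
        table = cmp.pass_rate_table(
            calc, meas, [(3, 2), (3, 1), (2, 2), (1, 1), (0.5, 0.5)], normalization_dose=10.0
        )
        p = dict(zip(table["criterion"], table["pass_rate_pct"]))
        assert p["3%/2 mm"] >= p["2%/2 mm"] >= p["1%/1 mm"] >= p["0.5%/0.5 mm"]
        assert p["3%/2 mm"] >= p["3%/1 mm"]


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        d = cmp.dvh(grid(8.0), normalization=16.0)
        assert d.volume_pct[d.dose_pct <= 50.0].min() == 100.0
        assert d.volume_pct[d.dose_pct > 50.0].max() == 0.0

    def test_linear_ramp_is_linear(self):
        n = 16**3
        data = np.linspace(0.0, 16.0, n).reshape(16, 16, 16)
        d = cmp.dvh(DoseGrid(data, GridGeometry((0, 0, 0), (1, 1, 1), (16, 16, 16))), 16.0)
        at50 = d.volume_pct[np.argmin(np.abs(d.dose_pct - 50.0))]
        assert at50 == pytest.approx(50.0, abs=1.0)
        assert d.volume_pct[0] == 100.0
        assert np.all(np.diff(d.volume_pct) <= 0)


class TestDDDVH:
    def test_identical_distributions_zero(self):
        g = smooth_pair(4)[0]
        _, vals = cmp.dddvh(g, g, 10.0)
        np.testing.assert_array_equal(vals, 0.0)

    def test_one_percent_shift_reads_001(self):
        # move exactly 1% of voxels from one bin to another
        data = np.full(GEOM.shape, 5.0)
        n = data.size
        k = int(round(0.01 * n))
        shifted = data.copy().ravel()
        shifted[:k] = 7.5
        m = DoseGrid(shifted.reshape(GEOM.shape), GEOM)
        c = DoseGrid(data, GEOM)
        edges, vals = cmp.dddvh(m, c, normalization=10.0, bin_width_pct=10.0)
        assert vals.max() == pytest.approx(k / n, abs=1e-12)
        assert vals.min() == pytest.approx(-k / n, abs=1e-12)

    def test_bins_sum_to_zero_and_antisymmetry(self):
        m, c = smooth_pair(5, shift=0.4)
        edges, vals = cmp.dddvh(m, c, 10.0)
        assert vals.sum() == pytest.approx(0.0, abs=1e-15)
        _, swapped = cmp.dddvh(c, m, 10.0)
        np.testing.assert_allclose(swapped, -vals, atol=1e-15)


class TestD4:
    def test_constant_ratio(self):
        c, _ = smooth_pair(6)
        c = DoseGrid(c.data + 1.0, GEOM)  # keep calculated > 0
        m = DoseGrid(1.02 * c.data, GEOM)
        d4 = cmp.d4_diagram(m, c, normalization=11.0)
        np.testing.assert_allclose(d4.mean_diff_pct, 2.0, rtol=1e-9)
        np.testing.assert_allclose(d4.sd_diff_pct, 0.0, atol=1e-9)
        assert d4.n.sum() == c.data.size

    def test_identical_grids_zero(self):
        c = grid(5.0)
        d4 = cmp.d4_diagram(c, c, 10.0)
        np.testing.assert_allclose(d4.mean_diff_pct, 0.0, atol=1e-12)

    def test_low_dose_bins_inflate_percent_sd(self):
        rng = np.random.default_rng(8)
        base = np.linspace(0.5, 16.0, GEOM.shape[0])[:, None, None] * np.ones(GEOM.shape)
        c = DoseGrid(base, GEOM)
        m = DoseGrid(base + 0.01 * 16.0 * rng.standard_normal(GEOM.shape), GEOM)
        d4 = cmp.d4_diagram(m, c, normalization=16.0)
        low = d4.sd_diff_pct[d4.bin_centers_pct < 20.0]
        high = d4.sd_diff_pct[d4.bin_centers_pct > 60.0]
        assert low.max() > 10.0  # percent differences blow up at low dose
        assert high.max() < 3.0

    def test_zero_calculated_dose_excluded_and_counted(self):
        c = DoseGrid(np.where(np.arange(GEOM.shape[0])[:, None, None] == 0, 0.0, 8.0)
                     * np.ones(GEOM.shape), GEOM)
        m = DoseGrid(c.data * 1.01, GEOM)
        d4 = cmp.d4_diagram(m, c, 16.0)
        assert d4.excluded_zero_dose == GEOM.shape[1] * GEOM.shape[2]
        assert d4.n.sum() + d4.excluded_zero_dose == c.data.size


class TestProfilesAndContours:
    def test_profile_through_single_shot_peaks_at_isocenter(self):
        import gammagel as gg
        from gammagel.phantom import PlanSpec, ShotSpec

        plan = PlanSpec((ShotSpec((100.0, 100.0, 100.0), 18.0),))
        geom = GridGeometry((80.0, 80.0, 80.0), (1.0, 1.0, 1.0), (41, 41, 41))
        field = gg.generate_calculated_dose(plan, geom)
        prof = cmp.line_profile(field, (80.0, 100.0, 100.0), (120.0, 100.0, 100.0), 0.5)
        assert prof.distance_mm[np.nanargmax(prof.dose)] == pytest.approx(20.0, abs=1.0)

    def test_profile_of_constant_field_is_constant(self):
        prof = cmp.line_profile(grid(4.0), (0.0, 0.0, 7.0), (14.0, 14.0, 7.0), 0.5)
        np.testing.assert_allclose(prof.dose, 4.0, rtol=1e-12)

    def test_radial_contour_roundness(self):
        geom = GridGeometry((-20.0, -20.0, 0.0), (0.5, 0.5, 1.0), (81, 81, 1))
        x, y, _ = geom.meshgrid_mm()
        plane = DoseGrid(10.0 * np.exp(-(x**2 + y**2) / 100.0), geom)
        contours = cmp.isodose_contours(plane, [5.0])
        assert len(contours[5.0]) == 1
        radii = np.linalg.norm(contours[5.0][0], axis=1)
        assert radii.std() < 0.25  # half the in-plane voxel spacing

    def test_level_above_max_is_empty(self):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (9, 9, 1))
        plane = DoseGrid(np.random.default_rng(0).uniform(0, 5, (9, 9, 1)), geom)
        assert cmp.isodose_contours(plane, [99.0])[99.0] == []

    def test_gel_study_contour_levels(self):
        levels = [cmp.relative_to_absolute(p, 16.0) for p in (5, 26, 50, 70, 90)]
        assert levels == pytest.approx([0.8, 4.16, 8.0, 11.2, 14.4])


class TestRelativeToAbsolute:
    @pytest.mark.parametrize(
        "pct,norm,expected", [(50, 16, 8.0), (80, 16, 12.8), (100, 7.3, 7.3), (90, 4, 3.6)]
    )
    def test_worked_conversions(self, pct, norm, expected):
        assert cmp.relative_to_absolute(pct, norm) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_normalization_rejected(self):
        with pytest.raises(ValueError):
            cmp.relative_to_absolute(50.0, 0.0)
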