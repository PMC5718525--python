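"""Grid container, resampling, subvolume and plane extraction."""

import numpy as np
import pytest

import gammagel as gg
from gammagel.geometry import Box, DoseGrid, GridGeometry, sample_at
from gammagel.phantom import evaluate_plan_dose


def make_grid(fn, origin=(0, 0, 0), spacing=(2.5, 2.5, 2.5), shape=(17, 17, 17)):
    geom = GridGeometry(origin, spacing, shape)
    x, y, z = geom.meshgrid_mm()
    return DoseGrid(fn(x, y, z), geom)


class TestGridGeometry:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), (1, -1, 1), (4, 4, 4))
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), (1, 1, 1), (4, 0, 4))

    def test_extent_is_voxel_center_inclusive(self):
        geom = GridGeometry((10, 20, 30), (2, 2, 2), (5, 5, 5))
        assert geom.extent == ((10, 18), (20, 28), (30, 38))


class TestResample:
    def test_constant_field_reproduced(self):
        grid = make_grid(lambda x, y, z: np.full_like(x, 3.5))
        target = GridGeometry((5.0, 5.0, 5.0), (1.0, 1.0, 1.0), (20, 20, 20))
        out = gg.resample(grid, target)
        np.testing.assert_allclose(out.data, 3.5)

    def test_affine_field_exact(self):
        # trilinear interpolation reproduces affine fields exactly
        grid = make_grid(lambda x, y, z: 0.7 * x + 0.1 * y - 0.3 * z + 2.0)
        target = GridGeometry((2.0, 3.0, 4.0), (1.0, 1.0, 1.0), (30, 30, 30))
        out = gg.resample(grid, target)
        x, y, z = target.meshgrid_mm()
        np.testing.assert_allclose(out.data, 0.7 * x + 0.1 * y - 0.3 * z + 2.0, atol=1e-12)

    @staticmethod
    def second_order_bound(plan, scale, spacing):
        """h^2/8 * max|f_aa| per axis of the analytic field, estimated by
        finite differences on a 0.5 mm probe lattice around the shots."""
        probe = GridGeometry((60.0, 55.0, 84.0), (0.5, 0.5, 0.5), (121, 151, 61))
        x, y, z = probe.meshgrid_mm()
        f = evaluate_plan_dose(plan, np.stack([x, y, z], axis=-1)) * scale
        return sum(
            spacing[a] ** 2 / 8.0 * np.abs(np.diff(f, 2, axis=a)).max() / 0.25
            for a in range(3)
        )

    def test_three_shot_field_within_second_order_bound(self, plan, calc_grid):
        # 2.5 mm -> 1 mm against direct evaluation of the generator
        target = GridGeometry((80.0, 80.0, 95.0), (1.0, 1.0, 1.0), (25, 25, 12))
        out = gg.resample(calc_grid, target)
        x, y, z = target.meshgrid_mm()
        analytic = evaluate_plan_dose(plan, np.stack([x, y, z], axis=-1))
        analytic *= calc_grid.meta["dose_scale"]
        err = np.abs(out.data - analytic).max()
        bound = self.second_order_bound(plan, calc_grid.meta["dose_scale"], (2.5,) * 3)
        assert err < bound

    def test_three_shot_field_well_sampled_below_half_percent(self, plan, calc_grid):
        # a source lattice resolving the sharpest shot penumbra: < 0.5% of max
        src = GridGeometry((75.0, 75.0, 92.0), (0.35, 0.35, 0.35), (101, 101, 49))
        fine = gg.generate_delivered_dose(plan, src, calc_grid)
        target = GridGeometry((80.0, 80.0, 95.0), (1.0, 1.0, 1.0), (25, 25, 12))
        out = gg.resample(fine, target)
        x, y, z = target.meshgrid_mm()
        analytic = evaluate_plan_dose(plan, np.stack([x, y, z], axis=-1))
        analytic *= calc_grid.meta["dose_scale"]
        assert np.abs(out.data - analytic).max() < 0.005 * calc_grid.max()

    def test_values_stay_within_source_range(self, calc_grid):
        target = GridGeometry((70.0, 70.0, 90.0), (0.7, 0.7, 0.7), (40, 40, 30))
        out = gg.resample(calc_grid, target)
        assert np.nanmin(out.data) >= np.nanmin(calc_grid.data) - 1e-12
        assert np.nanmax(out.data) <= np.nanmax(calc_grid.data) + 1e-12

    def test_round_trip_exact_on_aligned_divisor_lattice(self, calc_grid):
        # a 0.5 mm lattice sharing the 2.5 mm origins contains every source
        # node, so fine -> back is lossless
        fine = GridGeometry((55.0, 55.0, 55.0), (0.5, 0.5, 0.5), (181, 181, 181))
        sub = gg.extract_subvolume(calc_grid, Box((55, 55, 55), (145, 145, 145)))
        back = gg.resample(gg.resample(sub, fine), sub.geometry)
        np.testing.assert_allclose(back.data, sub.data, atol=1e-10)

    def test_round_trip_within_second_order_bound(self, plan, calc_grid):
        fine = GridGeometry((40.0, 40.0, 40.0), (1.0, 1.0, 1.0), (120, 120, 120))
        back = gg.resample(gg.resample(calc_grid, fine), calc_grid.geometry)
        inner = back.valid
        err = np.abs(back.data[inner] - calc_grid.data[inner]).max()
        bound = self.second_order_bound(plan, calc_grid.meta["dose_scale"], (2.5,) * 3)
        assert err < bound

    def test_outside_support_marked_nodata(self):
        grid = make_grid(lambda x, y, z: x, shape=(5, 5, 5))
        target = GridGeometry((-5.0, 0.0, 0.0), (2.5, 2.5, 2.5), (5, 5, 5))
        out = gg.resample(grid, target)
        assert np.isnan(out.data[0]).all() and np.isfinite(out.data[-1]).all()

    def test_disjoint_extent_is_error(self):
        grid = make_grid(lambda x, y, z: x, shape=(5, 5, 5))
        target = GridGeometry((100.0, 0.0, 0.0), (1.0, 1.0, 1.0), (5, 5, 5))
        with pytest.raises(ValueError, match="disjoint"):
            gg.resample(grid, target)


class TestSubvolume:
    def test_study_box_lattice_count(self):
        # inclusive [70,115]x[65,125]x[90,114] on a 1 mm integer lattice
        grid = DoseGrid(
            np.zeros((201, 201, 201)), GridGeometry((0, 0, 0), (1, 1, 1), (201, 201, 201))
        )
        sub = gg.extract_subvolume(grid, Box((70, 65, 90), (115, 125, 114)))
        assert sub.geometry.shape == (46, 61, 25)
        assert sub.geometry.origin == (70.0, 65.0, 90.0)

    def test_full_extent_is_identity(self, calc_grid):
        ext = calc_grid.geometry.extent
        sub = gg.extract_subvolume(
            calc_grid, Box(tuple(e[0] for e in ext), tuple(e[1] for e in ext))
        )
        np.testing.assert_array_equal(sub.data, calc_grid.data)

    def test_single_voxel_box(self):
        grid = DoseGrid(np.arange(27.0).reshape(3, 3, 3),
                        GridGeometry((0, 0, 0), (1, 1, 1), (3, 3, 3)))
        sub = gg.extract_subvolume(grid, Box((0.6, 0.6, 0.6), (1.4, 1.4, 1.4)))
        assert sub.geometry.shape == (1, 1, 1)
        assert sub.data[0, 0, 0] == grid.data[1, 1, 1]

    def test_empty_box_is_error(self):
        grid = DoseGrid(np.zeros((3, 3, 3)), GridGeometry((0, 0, 0), (1, 1, 1), (3, 3, 3)))
        with pytest.raises(ValueError, match="no voxel centres"):
            gg.extract_subvolume(grid, Box((0.1, 0, 0), (0.4, 2, 2)))


class TestExtractPlane:
    def test_aligned_slice_bit_exact(self, calc_grid):
        # Z = 102.5 mm is a slice centre of the 2.5 mm grid starting at 30
        plane = gg.extract_plane(calc_grid, "Z", 102.5)
        k = int(round((102.5 - 30.0) / 2.5))
        np.testing.assert_array_equal(plane.data[:, :, 0], calc_grid.data[:, :, k])

    def test_midway_is_mean_for_linear_field(self):
        grid = make_grid(lambda x, y, z: 2.0 * z, spacing=(1, 1, 2), shape=(4, 4, 6))
        plane = gg.extract_plane(grid, "Z", 5.0)  # midway between z=4 and z=6
        np.testing.assert_allclose(plane.data, 10.0)

    def test_three_shot_plane_close_to_analytic(self, plan, calc_grid):
        # z = 101 mm falls between 2.5 mm slices; the interpolated plane must
        # track the analytic field to within 1% of the maximum dose
        plane = gg.extract_plane(calc_grid, "Z", 101.0)
        x, y, z = plane.geometry.meshgrid_mm()
        analytic = evaluate_plan_dose(plan, np.stack([x, y, z], axis=-1))
        analytic *= calc_grid.meta["dose_scale"]
        assert np.abs(plane.data - analytic).max() < 0.01 * calc_grid.max()

    def test_out_of_extent_is_error(self, calc_grid):
        with pytest.raises(ValueError, match="outside"):
            gg.extract_plane(calc_grid, "Z", 500.0)


def test_subvolume_commutes_with_aligned_resample(calc_grid):
    box = Box((70.0, 65.0, 90.0), (115.0, 125.0, 115.0))
    fine = GridGeometry((70.0, 65.0, 90.0), (1.0, 1.0, 1.0), (46, 61, 26))
    a = gg.resample(gg.extract_subvolume(calc_grid, box), fine)
    b = gg.extract_subvolume(gg.resample(calc_grid, fine), box)
    np.testing.assert_allclose(a.data, b.data, atol=1e-10)


def test_sample_at_matches_voxel_centers(calc_grid):
    geom = calc_grid.geometry
    pts = np.array([[50.0, 50.0, 50.0], [102.5, 87.5, 102.5]])
    vals = sample_at(calc_grid, pts)
    idx = np.rint(geom.to_index(pts)).astype(int)
    expected = calc_grid.data[tuple(idx.T)]
    np.testing.assert_allclose(vals, expected, rtol=1e-12)
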