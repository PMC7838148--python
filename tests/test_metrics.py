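"""Level-set regions, characteristic distances, gradient clouds, front speed."""

import numpy as np
import pytest

import glioextent as ge
from glioextent.analytic import SQRT6, limit_inverse, limit_profile
from glioextent.discretization import ScalarField, build_grid
from glioextent.metrics import (
    GradientCloud,
    characteristic_distance,
    front_speed,
    gradient_cloud,
    surface_measure,
    symmetric_difference,
    threshold_region,
)


def _disk_field(grid, radius, center=None, hi=0.9):
    center = center or tuple(e / 2 for e in grid.extents)
    mesh = grid.node_mesh()
    r2 = sum((m - c) ** 2 for m, c in zip(mesh, center))
    return ScalarField(grid, np.where(r2 <= radius**2, hi, 0.0))


def _interval_field(grid, a, b):
    x = grid.node_positions(0)
    return ScalarField(grid, np.where((x >= a) & (x <= b), 0.9, 0.0))


class TestThresholdRegion:
    def test_zero_field_empty(self):
        grid = build_grid((10.0,), (20,))
        A = threshold_region(ScalarField.constant(grid, 0.0), 0.16)
        assert A.is_empty and A.volume == 0.0

    def test_limit_profile_region_ends_at_inverse_position(self):
        # front profile on a fine grid: the visible region ends at the
        # closed-form threshold position x(0.16) ~ 0.9931
        grid = build_grid((40.0,), (4000,))
        x = grid.node_positions(0) - 20.0
        A = threshold_region(ScalarField(grid, limit_profile(x)), 0.16)
        # region is [-20, x(0.16)] within the shifted domain
        expected = limit_inverse(0.16) + 20.0
        assert A.volume == pytest.approx(expected, abs=2 * grid.spacing[0])
        assert limit_inverse(0.16) == pytest.approx(SQRT6 * np.log(1.5))

    def test_disk_volume_close_to_geometry(self):
        grid = build_grid((20.0, 20.0), (128, 128))
        A = threshold_region(_disk_field(grid, 6.0), 0.16)
        cell_layer = 2.0 * np.pi * 6.0 * grid.spacing[0]
        assert abs(A.volume - np.pi * 36.0) < cell_layer


class TestSymmetricDifference:
    def test_identical_regions(self):
        grid = build_grid((10.0,), (50,))
        A = threshold_region(_interval_field(grid, 2.0, 5.0), 0.16)
        assert symmetric_difference(A, A) == 0.0

    def test_disjoint_regions_add(self):
        grid = build_grid((100.0,), (1000,))
        A = threshold_region(_interval_field(grid, 10.0, 20.0), 0.16)
        B = threshold_region(_interval_field(grid, 50.0, 70.0), 0.16)
        assert symmetric_difference(A, B) == pytest.approx(
            A.volume + B.volume, rel=1e-12
        )

    def test_interval_arithmetic(self):
        grid = build_grid((100.0,), (1000,))
        A = threshold_region(_interval_field(grid, 0.0, 10.0), 0.16)
        B = threshold_region(_interval_field(grid, 0.0, 12.0), 0.16)
        assert symmetric_difference(A, B) == pytest.approx(2.0, abs=0.2)

    def test_grid_mismatch_rejected(self):
        A = threshold_region(
            _interval_field(build_grid((10.0,), (10,)), 2.0, 5.0), 0.16
        )
        B = threshold_region(
            _interval_field(build_grid((10.0,), (20,)), 2.0, 5.0), 0.16
        )
        with pytest.raises(ValueError):
            symmetric_difference(A, B)

    def test_growing_apart_never_decreases(self):
        grid = build_grid((100.0,), (500,))
        A = threshold_region(_interval_field(grid, 40.0, 50.0), 0.16)
        prev = -1.0
        for b in (50.0, 54.0, 58.0, 62.0):
            B = threshold_region(_interval_field(grid, 40.0, b), 0.16)
            sd = symmetric_difference(A, B)
            assert sd >= prev
            prev = sd


class TestCharacteristicDistance:
    def test_1d_interval_pair(self):
        grid = build_grid((100.0,), (1000,))
        A = threshold_region(_interval_field(grid, 0.0, 10.0), 0.16)
        B = threshold_region(_interval_field(grid, 0.0, 12.0), 0.16)
        assert characteristic_distance(A, B) == pytest.approx(1.0, abs=0.1)

    def test_2d_disk_annulus(self):
        grid = build_grid((50.0, 50.0), (256, 256))
        A = threshold_region(_disk_field(grid, 10.0), 0.16)
        B = threshold_region(_disk_field(grid, 11.0), 0.16)
        # annulus area over reference circumference: 21 pi / 20 pi
        assert characteristic_distance(A, B, "spherical") == pytest.approx(
            1.05, rel=0.05
        )

    def test_spherical_and_exact_modes_agree_for_balls(self):
        grid = build_grid((20.0, 20.0), (160, 160))  # 96 cells per diameter
        A = threshold_region(_disk_field(grid, 6.0), 0.16)
        B = threshold_region(_disk_field(grid, 6.5), 0.16)
        sph = characteristic_distance(A, B, "spherical")
        exa = characteristic_distance(A, B, "exact")
        assert abs(sph - exa) / sph < 0.1

    def test_empty_reference_rejected(self):
        grid = build_grid((10.0,), (20,))
        empty = threshold_region(ScalarField.constant(grid, 0.0), 0.16)
        full = threshold_region(ScalarField.constant(grid, 0.9), 0.5)
        with pytest.raises(ValueError):
            characteristic_distance(empty, full)

    def test_3d_exact_surface_measure(self):
        # smooth radial sigmoid whose theta level-set is a sphere of r = 6
        grid = build_grid((20.0, 20.0, 20.0), (40, 40, 40))
        mesh = grid.node_mesh()
        r = np.sqrt(sum((m - 10.0) ** 2 for m in mesh))
        u = ScalarField(grid, 1.0 / (1.0 + np.exp((r - 6.0) / 0.8)))
        A = threshold_region(u, 0.5)
        exact = surface_measure(A, "exact")
        assert exact == pytest.approx(4.0 * np.pi * 36.0, rel=0.05)


class TestGradientCloud:
    def test_exact_profile_lies_on_reference_curve(self):
        grid = build_grid((40.0,), (4000,))
        x = grid.node_positions(0) - 20.0
        cloud = gradient_cloud(ScalarField(grid, limit_profile(x)))
        dev = cloud.deviation()
        assert dev["max"] < grid.spacing[0] ** 2 * 10.0

    def test_forward_simulation_approaches_curve_with_time(self):
        # the gradient distribution converges to the analytic penalty curve
        # only at late times
        grid = ge.build_grid((120.0,), (600,))
        field = ge.homogeneous_field(grid, 1.0)
        ic = __import__(
            "glioextent.scenarios", fromlist=["gaussian_ic"]
        ).gaussian_ic(grid, 1.0, 1.0)
        controls = ge.TimeControls(t_end=16.0, dt=0.1, checkpoints=(5.0, 16.0))
        traj, _ = ge.solve_forward(grid, field, ge.ModelParams(), ic, controls)
        devs = [gradient_cloud(f).deviation()["mean"] for _, f in traj]
        assert devs[-1] < devs[0]

    def test_random_medium_preserves_curve_shape(self):
        # inhomogeneity scatters the cloud without destroying the
        # polynomial amplitude-gradient relation: the bin-averaged cloud
        # still tracks the reference curve, and the scatter stays bounded
        grid = ge.build_grid((200.0,), (1000,))
        field = ge.random_isotropic_field(grid, 0.8, seed=5)
        ic = __import__(
            "glioextent.scenarios", fromlist=["gaussian_ic"]
        ).gaussian_ic(grid, 1.0, 1.0)
        traj, _ = ge.solve_forward(
            grid,
            field,
            ge.ModelParams(),
            ic,
            ge.TimeControls(t_end=20.0, dt=0.1, checkpoints=(16.0, 18.0, 20.0)),
        )
        clouds = [gradient_cloud(f) for _, f in traj]
        u = np.concatenate([c.u for c in clouds])
        g = np.concatenate([c.grad_mag for c in clouds])
        sel = (u >= 0.05) & (u <= 0.95)
        u, g = u[sel], g[sel]
        assert np.abs(g - GradientCloud.reference(u)).max() < 0.25
        bins = np.linspace(0.05, 0.95, 10)
        which = np.digitize(u, bins)
        centers, means = [], []
        for k in range(1, len(bins)):
            m = which == k
            if m.sum() > 3:
                centers.append(0.5 * (bins[k - 1] + bins[k]))
                means.append(g[m].mean())
        corr = np.corrcoef(means, GradientCloud.reference(np.array(centers)))[0, 1]
        assert corr > 0.9

    def test_csv_export(self, tmp_path):
        grid = build_grid((10.0,), (100,))
        x = grid.node_positions(0) - 5.0
        cloud = gradient_cloud(ScalarField(grid, limit_profile(x)))
        path = tmp_path / "cloud.csv"
        cloud.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (99, 3)


class TestFrontSpeed:
    def test_rigid_translation_exact(self):
        grid = build_grid((100.0,), (500,))
        x = grid.node_positions(0)
        traj = []
        speed = 1.7
        for t in np.arange(0.0, 10.0, 1.0):
            traj.append((t, ScalarField(grid, limit_profile(x - 20.0 - speed * t))))
        assert front_speed(traj, level=0.5) == pytest.approx(speed, abs=1e-10)

    def test_static_profile_zero_speed(self):
        grid = build_grid((100.0,), (500,))
        x = grid.node_positions(0)
        fld = ScalarField(grid, limit_profile(x - 30.0))
        traj = [(float(t), fld) for t in range(6)]
        assert front_speed(traj) == pytest.approx(0.0, abs=1e-12)

    def test_missing_crossing_reported(self):
        grid = build_grid((10.0,), (10,))
        traj = [(0.0, ScalarField.constant(grid, 0.1))] * 4
        with pytest.raises(ValueError, match="crossing"):
            front_speed(traj, level=0.5)

    def test_nondimensional_fisher_speed(self, forward_1d_reference):
        _, _, trajectory, _ = forward_1d_reference
        speed = front_speed(trajectory, level=0.5, fit_window=(10.0, 20.0))
        assert speed == pytest.approx(2.0, rel=0.05)
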