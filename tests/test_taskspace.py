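import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stepshape.taskspace import (
    LimbModel,
    ellipse_area,
    forward_heel_height,
    heel_height_from_recorded,
    model_angles_from_recorded,
    project_variances,
    task_space_basis,
    tolerance_cost,
)


class TestForwardModel:
    @pytest.mark.parametrize(
        "hip_z,thigh,shank,hip_a_deg,knee_a_deg,expected",
        [
            (0.90, 0.40, 0.40, 0.0, 0.0, 0.90),
            (0.90, 0.40, 0.40, 90.0, -90.0, 1.30),
            (0.85, 0.42, 0.40, 30.0, 30.0, 0.85 + 0.42 * np.sin(np.pi / 6) + 0.40 * np.sin(np.pi / 3)),
        ],
    )
    def test_hand_evaluations(self, hip_z, thigh, shank, hip_a_deg, knee_a_deg, expected):
        model = LimbModel(hip_z, thigh, shank)
        got = forward_heel_height(model, np.deg2rad(hip_a_deg), np.deg2rad(knee_a_deg))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_angle_bridge_standing(self, limb):
        # zero flexion: thigh straight down, knee extended -> heel at hip_z - thigh - shank
        h = heel_height_from_recorded(limb, 0.0, 0.0)
        assert h == pytest.approx(limb.hip_z_m - limb.thigh_l_m - limb.shank_l_m)

    def test_angle_bridge_right_angles(self, limb):
        # hip flexed 90 deg (thigh horizontal), knee extended: shank continues horizontal
        assert heel_height_from_recorded(limb, 90.0, 0.0) == pytest.approx(limb.hip_z_m)
        # knee then flexed 90 deg: shank points straight up
        assert heel_height_from_recorded(limb, 90.0, 90.0) == pytest.approx(
            limb.hip_z_m + limb.shank_l_m
        )

    def test_bridge_convention(self):
        ma = model_angles_from_recorded(90.0, 30.0)
        assert ma.hip_a_rad == pytest.approx(0.0)
        assert ma.knee_a_rad == pytest.approx(np.deg2rad(30.0))

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            LimbModel(0.9, -0.4, 0.4)


class TestBasis:
    def test_gradient_hand_value(self):
        # thigh = shank = L, hip_a = 0, knee_a = 0 (i.e. hip flexion 90, knee 0)
        model = LimbModel(0.9, 0.4, 0.4)
        pts = np.tile([90.0, 0.0], (3, 1)) + np.array([[0, 0], [0.01, 0], [0, 0.01]])
        basis = task_space_basis(pts, model)
        expected = np.array([2.0, 1.0]) / np.sqrt(5.0)
        assert np.allclose(np.abs(basis.e_orth), expected, atol=1e-3)

    def test_equivalent_direction_is_level(self, limb, rng):
        pts = rng.normal([20.0, 50.0], 2.0, size=(10, 2))
        basis = task_space_basis(pts, limb)
        # central difference of heel height along e_eq vanishes at the mean
        h = 1e-5
        mean = np.array(basis.ref_config)
        up = mean + h * basis.e_eq
        dn = mean - h * basis.e_eq
        d = heel_height_from_recorded(limb, up[0], up[1]) - heel_height_from_recorded(
            limb, dn[0], dn[1]
        )
        assert abs(d) < 1e-9
        assert basis.e_eq @ basis.e_orth == pytest.approx(0.0, abs=1e-12)

    def test_contour_points_have_no_orthogonal_variance(self, limb):
        # construct points exactly on a constant-height contour by solving
        # for the knee angle that restores the mean height at each hip angle
        from scipy.optimize import brentq

        target = heel_height_from_recorded(limb, 20.0, 50.0)
        hips = np.linspace(17.0, 23.0, 9)
        knees = [
            brentq(lambda k: heel_height_from_recorded(limb, h, k) - target, 20.0, 80.0)
            for h in hips
        ]
        pts = np.column_stack([hips, knees])
        basis = task_space_basis(pts, limb)
        var_eq, var_orth = project_variances(pts, basis)
        assert var_orth < 1e-3 * var_eq

    def test_singular_configuration_rejected(self):
        model = LimbModel(0.9, 0.4, 0.4)
        # hip_a = 90 deg (hip flexion 180), knee_a = 180: gradient vanishes
        pts = np.tile([180.0, 180.0], (3, 1))
        with pytest.raises(ValueError):
            task_space_basis(pts, model)


class TestVariances:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_identity(self, seed):
        rng = np.random.default_rng(seed)
        limb = LimbModel(0.9, 0.4, 0.42)
        pts = rng.normal([25.0, 55.0], [3.0, 5.0], size=(rng.integers(3, 40), 2))
        basis = task_space_basis(pts, limb)
        var_eq, var_orth = project_variances(pts, basis)
        centered = pts - pts.mean(axis=0)
        total = np.var(centered[:, 0], ddof=1) + np.var(centered[:, 1], ddof=1)
        assert var_eq + var_orth == pytest.approx(total, rel=1e-10)

    def test_identical_points(self, limb):
        pts = np.tile([20.0, 50.0], (5, 1))
        basis = task_space_basis(pts, limb)
        assert project_variances(pts, basis) == (0.0, 0.0)

    def test_cloud_along_equivalent_direction(self, limb):
        basis = task_space_basis(np.array([[19.0, 49], [20, 50], [21, 51.0]]), limb)
        pts = np.array([20.0, 50.0]) + np.linspace(-3, 3, 11)[:, None] * basis.e_eq
        basis2 = task_space_basis(pts, limb)
        var_eq, var_orth = project_variances(pts, basis2)
        assert var_orth < 1e-6 * var_eq


class TestEllipse:
    def test_collinear_area_zero(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        assert ellipse_area(pts) == pytest.approx(0.0, abs=1e-9)

    def test_scaling(self, rng):
        pts = rng.normal(size=(200, 2))
        assert ellipse_area(2 * pts) == pytest.approx(4 * ellipse_area(pts), rel=1e-9)

    def test_standard_normal_calibration(self, rng):
        pts = rng.standard_normal((20000, 2))
        expected = np.pi * stats.chi2.ppf(0.85, 2)
        assert ellipse_area(pts) == pytest.approx(expected, rel=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ellipse_area(np.zeros((2, 2)))


class TestToleranceCost:
    def test_zero_scatter(self, limb):
        pts = np.tile([20.0, 50.0], (5, 1))
        assert tolerance_cost(pts, limb) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_and_permutation_invariant(self, limb, rng):
        pts = rng.normal([25.0, 55.0], 3.0, size=(10, 2))
        t1 = tolerance_cost(pts, limb, 20.0, 1.0)
        t2 = tolerance_cost(pts[::-1], limb, 20.0, 1.0)
        assert t1 >= 0
        assert t1 == pytest.approx(t2, abs=1e-15)

    def test_steeper_region_costs_more(self, limb, rng):
        # same cloud shape placed where the height map is flat vs steep:
        # brute-force grid evaluation says the steeper placement has more
        # removable outcome SD
        cloud = rng.normal(0.0, 2.0, size=(12, 2))
        # near (170, 5) both gradient components ~cos(80 deg): almost level
        flat = cloud + np.array([170.0, 5.0])
        steep = cloud + np.array([30.0, 10.0])
        assert tolerance_cost(steep, limb, 5.0, 0.5) > tolerance_cost(flat, limb, 5.0, 0.5)

    def test_already_optimal_location(self, limb, rng):
        # translate the cloud to the grid's best location; the cost there is ~0
        cloud = rng.normal([30.0, 20.0], 2.0, size=(10, 2))
        c0 = tolerance_cost(cloud, limb, 30.0, 1.0)
        offsets = np.arange(-30.0, 30.5, 1.0)

        def sd_at(off):
            p = cloud + off
            return heel_height_from_recorded(limb, p[:, 0], p[:, 1]).std(ddof=1)

        grid = [(sd_at(np.array([dx, dy])), dx, dy) for dx in offsets for dy in offsets]
        _, dx, dy = min(grid)
        moved = cloud + np.array([dx, dy])
        assert tolerance_cost(moved, limb, 5.0, 1.0) <= c0
        assert tolerance_cost(moved, limb, 1.0, 1.0) == pytest.approx(0.0, abs=1e-9)
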