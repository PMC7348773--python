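import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hingecal.kinematics import (AxisParams, ResidualWeights, SampleBatch,
                                 accel_residual, angular_deviation,
                                 axis_to_spherical, cost, gyro_residual,
                                 residual_jacobian, residual_vector,
                                 rotation_operator_K, spherical_to_axis)

W = ResidualWeights.from_w0(50.0)

angles = st.floats(-10.0, 10.0, allow_nan=False)


def finite_difference_jacobian(x, data, w, h=1e-7):
    """Central-difference oracle for the residual Jacobian."""
    x = np.asarray(x, dtype=float)
    cols = []
    for i in range(4):
        e = np.zeros(4)
        e[i] = h
        cols.append((residual_vector(x + e, data, w)
                     - residual_vector(x - e, data, w)) / (2 * h))
    return np.column_stack(cols)


class TestSphericalMap:
    @pytest.mark.parametrize("theta,phi,expected", [
        (0.0, 0.0, (1, 0, 0)),
        (math.pi / 2, 0.0, (0, 0, 1)),
        (0.0, math.pi / 2, (0, 1, 0)),   # the benchmark rig's true axis
    ])
    def test_reference_directions(self, theta, phi, expected):
        np.testing.assert_allclose(spherical_to_axis(theta, phi), expected,
                                   atol=1e-15)

    @given(angles, angles)
    @settings(max_examples=200, derandomize=True)
    def test_always_unit_norm(self, theta, phi):
        assert abs(np.linalg.norm(spherical_to_axis(theta, phi)) - 1.0) < 1e-12

    def test_pole_convention(self):
        assert axis_to_spherical((0, 0, 1)) == (math.pi / 2, 0.0)
        assert axis_to_spherical((0, 1, 0)) == pytest.approx((0.0, math.pi / 2))

    def test_round_trip_random_unit_vectors(self, rng):
        v = rng.standard_normal((100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        for j in v:
            theta, phi = axis_to_spherical(j)
            assert -math.pi / 2 <= theta <= math.pi / 2
            assert -math.pi < phi <= math.pi
            np.testing.assert_allclose(spherical_to_axis(theta, phi), j,
                                       atol=1e-9)

    @given(angles, angles, angles, angles)
    @settings(max_examples=100, derandomize=True)
    def test_flip_map_negates_only_second_axis(self, t1, p1, t2, p2):
        x = AxisParams(t1, p1, t2, p2)
        f = x.flipped()
        np.testing.assert_allclose(f.axis1(), x.axis1(), atol=1e-12)
        np.testing.assert_allclose(f.axis2(), -x.axis2(), atol=1e-12)


class TestRotationOperator:
    def test_zero_input_gives_zero_matrix(self):
        np.testing.assert_array_equal(rotation_operator_K((0, 0, 0), (0, 0, 0)),
                                      np.zeros((3, 3)))

    def test_pure_centripetal_spin_about_z(self):
        np.testing.assert_allclose(rotation_operator_K((0, 0, 1), (0, 0, 0)),
                                   np.diag([-1.0, -1.0, 0.0]))

    def test_matches_cross_product_identity(self, rng):
        """K(w, wd) r must equal w x (w x r) + wd x r."""
        for _ in range(20):
            w, wd, r = rng.standard_normal((3, 3))
            expected = np.cross(w, np.cross(w, r)) + np.cross(wd, r)
            np.testing.assert_allclose(rotation_operator_K(w, wd) @ r,
                                       expected, atol=1e-12)

    def test_symmetric_when_no_angular_acceleration(self, rng):
        K = rotation_operator_K(rng.standard_normal(3), np.zeros(3))
        np.testing.assert_allclose(K, K.T, atol=1e-15)


class TestResiduals:
    def test_gyro_residual_zero_for_matching_axes(self):
        x = AxisParams.from_axes((0, 1, 0), (0, 1, 0))
        assert gyro_residual(x, (1.0, 2.0, 3.0), (1.0, 2.0, 3.0), W) == \
            pytest.approx(0.0)

    def test_gyro_residual_unit_cross_product(self):
        x = AxisParams.from_axes((0, 1, 0), (1, 0, 0))
        w1 = ResidualWeights(1.0, 1.0)
        assert gyro_residual(x, (1, 0, 0), (0, 0, 0), w1) == pytest.approx(1.0)

    def test_gyro_residual_vanishes_on_stiff_trajectories(self, rng):
        """Under a constant relative rotation R, the pair (j1, R j1) zeroes
        the gyro residual for any j1 and any angular velocity."""
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=3).as_matrix()
        j1 = rng.standard_normal(3)
        j1 /= np.linalg.norm(j1)
        x = AxisParams.from_axes(j1, R @ j1)
        w1 = rng.standard_normal((25, 3))
        e = gyro_residual(x, w1, w1 @ R.T, W)
        np.testing.assert_allclose(e, 0.0, atol=1e-9)

    def test_accel_residual_cases(self):
        w1 = ResidualWeights(1.0, 1.0)
        x_same = AxisParams.from_axes((0, 1, 0), (0, 1, 0))
        a = (1.0, -2.0, 0.5)
        assert accel_residual(x_same, a, a, w1) == pytest.approx(0.0)
        x_rot = AxisParams.from_axes((0, 1, 0), (1, 0, 0))
        assert accel_residual(x_rot, (0, 9.82, 0), (9.82, 0, 0), w1) == \
            pytest.approx(0.0)

    def test_cost_is_squared_residual_norm(self, random_batch):
        x = AxisParams(0.3, -1.1, 0.8, 2.0)
        e = residual_vector(x, random_batch, W)
        assert cost(x, random_batch, W) == pytest.approx(float(e @ e))

    def test_cost_invariant_under_joint_sign_flip(self, random_batch, rng):
        """(j1, j2) and (-j1, -j2) describe the same physical axis and must
        give identical cost."""
        for _ in range(10):
            j1, j2 = rng.standard_normal((2, 3))
            j1 /= np.linalg.norm(j1)
            j2 /= np.linalg.norm(j2)
            v_pos = cost(AxisParams.from_axes(j1, j2), random_batch, W)
            v_neg = cost(AxisParams.from_axes(-j1, -j2), random_batch, W)
            assert v_pos == pytest.approx(v_neg, rel=1e-12)

    def test_empty_batch_cost_is_zero(self):
        empty = SampleBatch(np.empty(0), np.empty((0, 3)), np.empty((0, 3)),
                            np.empty((0, 3)), np.empty((0, 3)))
        assert cost(AxisParams(0.1, 0.2, 0.3, 0.4), empty, W) == 0.0


class TestJacobian:
    def test_matches_finite_differences(self, random_batch, rng):
        for _ in range(10):
            x = rng.uniform(-math.pi, math.pi, 4)
            J, e = residual_jacobian(x, random_batch, W)
            np.testing.assert_allclose(e, residual_vector(x, random_batch, W))
            J_fd = finite_difference_jacobian(x, random_batch, W)
            assert np.max(np.abs(J - J_fd)) < 1e-6

    def test_row_ordering_gyro_then_accel(self, random_batch):
        x = AxisParams(0.2, 0.4, -0.3, 1.0)
        J, e = residual_jacobian(x, random_batch, W)
        n = len(random_batch)
        assert J.shape == (2 * n, 4)
        np.testing.assert_allclose(
            e[:n], gyro_residual(x, random_batch.gyro1, random_batch.gyro2, W))

    def test_zero_accel_channels_zero_accel_rows(self, random_batch):
        x = AxisParams(0.2, 0.4, -0.3, 1.0)
        batch = SampleBatch(random_batch.times, random_batch.gyro1,
                            random_batch.gyro2,
                            np.zeros_like(random_batch.accel1),
                            np.zeros_like(random_batch.accel2))
        J, _ = residual_jacobian(x, batch, W)
        np.testing.assert_array_equal(J[len(batch):], 0.0)

    def test_zero_gyro_sample_gives_zero_row(self):
        """The gradient of ||y x j|| is singular at y x j = 0; the zero
        subgradient is used so stationary samples contribute zero rows."""
        batch = SampleBatch([0.0], np.zeros((1, 3)), np.zeros((1, 3)),
                            np.ones((1, 3)), np.ones((1, 3)))
        J, _ = residual_jacobian(AxisParams(0.1, 0.2, 0.3, 0.4), batch, W)
        np.testing.assert_array_equal(J[0], 0.0)


class TestAngularDeviation:
    @pytest.mark.parametrize("v1,v2,expected", [
        ((1, 0, 0), (1, 0, 0), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
    ])
    def test_reference_angles(self, v1, v2, expected):
        assert angular_deviation(v1, v2) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angular_deviation((0, 0, 0), (1, 0, 0))

    def test_clamps_rounding_noise(self):
        v = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        assert angular_deviation(v, v) == 0.0


class TestSampleBatch:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            SampleBatch([0.0, 0.02], np.zeros((2, 3)), np.zeros((1, 3)),
                        np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError):
            SampleBatch([0.0, 0.0], np.zeros((2, 3)), np.zeros((2, 3)),
                        np.zeros((2, 3)), np.zeros((2, 3)))
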