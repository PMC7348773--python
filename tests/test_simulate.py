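import dataclasses

import numpy as np
import pytest

from hingecal.kinematics import AxisParams, ResidualWeights, cost, gyro_residual
from hingecal.simulate import (SCENARIOS, SimConfig, build_scenario,
                               generate_trajectory, iter_seconds, motion_spec,
                               read_recording, synthesize_measurements,
                               write_recording)

ALL_MOTIONS = list(range(1, 15))


@pytest.fixture(scope="module", params=[1, 2, 3, 5, 6, 7, 10, 12, 14])
def truth(request, noisefree_cfg):
    return generate_trajectory(motion_spec(request.param, 8.0), noisefree_cfg)


class TestTrajectoryInvariants:
    def test_axis_transport_consistency(self, truth):
        """Both sensors must carry their axis onto the same global vector at
        every sample."""
        jg1 = np.einsum("nij,j->ni", truth.R1, truth.j1)
        jg2 = np.einsum("nij,j->ni", truth.R2, truth.j2)
        assert np.max(np.abs(jg1 - jg2)) < 1e-9

    def test_gyro_constraint_exact_at_true_axes(self, truth):
        n1 = np.linalg.norm(np.cross(truth.omega1, truth.j1), axis=1)
        n2 = np.linalg.norm(np.cross(truth.omega2, truth.j2), axis=1)
        assert np.max(np.abs(n1 - n2)) < 1e-9

    def test_rotations_are_orthonormal(self, truth):
        RtR = np.einsum("nji,njk->nik", truth.R1, truth.R1)
        assert np.max(np.abs(RtR - np.eye(3))) < 1e-12

    def test_closed_form_rates_match_finite_differences(self, truth):
        """d/dt R = [w]x R: differencing the orientations must reproduce the
        closed-form angular velocity to discretization accuracy."""
        dt = truth.times[1] - truth.times[0]
        Rd = (truth.R1[2:] - truth.R1[:-2]) / (2 * dt)
        Wx = np.einsum("nij,nkj->nik", Rd, truth.R1[1:-1])
        w_fd = np.stack([Wx[:, 2, 1], Wx[:, 0, 2], Wx[:, 1, 0]], axis=1)
        w_cf = np.einsum("nij,nj->ni", truth.R1[1:-1], truth.omega1[1:-1])
        scale = max(1.0, np.max(np.linalg.norm(w_cf, axis=1)))
        assert np.max(np.abs(w_fd - w_cf)) / scale < 5e-3


class TestMotionClasses:
    def test_stationary_is_at_rest(self, noisefree_cfg):
        t = generate_trajectory(motion_spec(1, 5.0), noisefree_cfg)
        assert np.all(t.omega1 == 0) and np.all(t.omega2 == 0)
        assert np.all(t.omegadot1 == 0) and np.all(t.a0 == 0)

    def test_stiff_rotation_has_constant_relative_orientation(self, noisefree_cfg):
        t = generate_trajectory(motion_spec(2, 5.0), noisefree_cfg)
        rel = np.einsum("nji,njk->nik", t.R1, t.R2)
        assert np.max(np.abs(rel - rel[0])) < 1e-9
        assert np.max(np.linalg.norm(t.omega1, axis=1)) > 0.1

    def test_sequential_rotation_moves_one_segment_at_a_time(self, noisefree_cfg):
        t = generate_trajectory(motion_spec(3, 8.0), noisefree_cfg)
        half = len(t) // 2
        rel = np.einsum("nji,njk->nik", t.R1, t.R2)
        # during the first half only segment 1 rotates: the relative
        # orientation changes while segment 2 is completely at rest
        d_rel_first = np.max(np.abs(rel[:half] - rel[0]))
        assert d_rel_first > 1e-3
        assert np.max(np.linalg.norm(t.omega2[: half // 2], axis=1)) < 1e-9
        assert np.max(np.linalg.norm(t.omega1[: half // 2], axis=1)) > 0.05

    def test_fast_variant_scales_rates(self, noisefree_cfg):
        slow = generate_trajectory(motion_spec(5, 8.0), noisefree_cfg)
        fast = generate_trajectory(motion_spec(12, 8.0), noisefree_cfg)
        r = (np.max(np.linalg.norm(fast.omega1, axis=1))
             / np.max(np.linalg.norm(slow.omega1, axis=1)))
        assert r == pytest.approx(3.0, rel=0.15)


class TestMeasurementSynthesis:
    def test_stationary_accel_reads_gravity(self, noisefree_cfg):
        t = generate_trajectory(motion_spec(1, 5.0), noisefree_cfg)
        b = synthesize_measurements(t, noisefree_cfg)
        norms = np.linalg.norm(b.accel1, axis=1)
        np.testing.assert_allclose(norms, 9.82, atol=1e-9)
        assert np.all(b.gyro1 == 0)

    def test_gyro_constraint_holds_on_noise_free_measurements(self, noisefree_cfg):
        t = generate_trajectory(motion_spec(5, 8.0), noisefree_cfg)
        b = synthesize_measurements(t, noisefree_cfg)
        x_true = AxisParams.from_axes(t.j1, t.j2)
        e = gyro_residual(x_true, b.gyro1, b.gyro2, ResidualWeights(1.0, 1.0))
        assert np.max(np.abs(e)) < 1e-9

    def test_accel_constraint_exact_with_zero_offsets(self, noisefree_cfg):
        cfg = dataclasses.replace(noisefree_cfg, r1=(0, 0, 0), r2=(0, 0, 0))
        t = generate_trajectory(motion_spec(5, 8.0), cfg)
        b = synthesize_measurements(t, cfg)
        x_true = AxisParams.from_axes(t.j1, t.j2)
        v = cost(x_true, b, ResidualWeights.from_w0(50.0))
        assert v < 1e-18 * len(b)

    def test_noise_reproducible_and_truth_independent_of_seed(self, sim_cfg):
        t = generate_trajectory(motion_spec(5, 4.0), sim_cfg)
        b1 = synthesize_measurements(t, sim_cfg)
        b2 = synthesize_measurements(t, sim_cfg)
        np.testing.assert_array_equal(b1.gyro1, b2.gyro1)
        cfg2 = dataclasses.replace(sim_cfg, seed=sim_cfg.seed + 1)
        t2 = generate_trajectory(motion_spec(5, 4.0), cfg2)
        np.testing.assert_array_equal(t.R1, t2.R1)
        b3 = synthesize_measurements(t2, cfg2)
        assert not np.array_equal(b1.gyro1, b3.gyro1)

    def test_bias_shifts_measurements_additively(self, noisefree_cfg):
        cfg_b = dataclasses.replace(noisefree_cfg, gyro_bias_1=(0.1, 0, 0),
                                    accel_bias_2=(0, 0, -1.0))
        t = generate_trajectory(motion_spec(5, 4.0), noisefree_cfg)
        b0 = synthesize_measurements(t, noisefree_cfg)
        b1 = synthesize_measurements(t, cfg_b)
        np.testing.assert_allclose(b1.gyro1 - b0.gyro1,
                                   np.tile([0.1, 0, 0], (len(t), 1)), atol=1e-12)
        np.testing.assert_allclose(b1.accel2 - b0.accel2,
                                   np.tile([0, 0, -1.0], (len(t), 1)), atol=1e-12)


class TestScenarios:
    def test_scenario_catalog(self):
        assert set(SCENARIOS) == {f"scenario{i}" for i in range(1, 5)}

    def test_scenario1_sample_bookkeeping(self, sim_cfg):
        """At the benchmark durations (14 x 50 s at 50 Hz) the cumulative
        count reaches 35000 samples at t = 700 s."""
        data = build_scenario("scenario1", sim_cfg, motion_duration=4.0)
        assert len(data.batch) == 14 * 4 * 50
        # full-scale bookkeeping, computed from the spec without simulating
        n_full = sum(int(round((e.stop - e.start) * 50.0 * 50))
                     for e in SCENARIOS["scenario1"].entries)
        assert n_full == 35000

    def test_scenario4_informative_motion_arrives_late(self, sim_cfg):
        data = build_scenario("scenario4", sim_cfg, motion_duration=4.0)
        informative = np.isin(data.labels, (3, 4, 5, 6, 7, 10, 11, 12, 13, 14))
        first = np.argmax(informative)
        assert first > len(data.labels) / 2

    def test_truncations_match_fractions(self, sim_cfg):
        data = build_scenario("scenario3", sim_cfg, motion_duration=10.0)
        n6 = int(np.sum(data.labels == 6))
        assert n6 == int(0.4 * 10.0 * sim_cfg.sample_rate)

    def test_iter_seconds_covers_batch(self, sim_cfg):
        data = build_scenario("scenario3", sim_cfg, motion_duration=4.0)
        chunks = list(iter_seconds(data.batch, sim_cfg.sample_rate))
        assert sum(len(c) for c in chunks) == len(data.batch)
        assert all(len(c) == 50 for c in chunks[:-1])


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path, sim_cfg):
        t = generate_trajectory(motion_spec(5, 2.0), sim_cfg)
        b = synthesize_measurements(t, sim_cfg)
        path = tmp_path / "rec.csv"
        write_recording(path, b)
        b2 = read_recording(path)
        np.testing.assert_allclose(b2.gyro1, b.gyro1, rtol=1e-8)
        np.testing.assert_allclose(b2.accel2, b.accel2, rtol=1e-8)

    def test_malformed_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,g1x\n0,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_recording(path)
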