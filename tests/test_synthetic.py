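"""Synthetic treadmill-gait simulator: protocol, kinematics, IMU synthesis."""

import hashlib

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitphase.synthetic import (
    GaitCondition,
    SubjectParams,
    generate_dataset,
    joint_trajectories,
    make_protocol,
    simulate_imu,
    simulate_session,
)


def _const_cond(v, duration=10.0, name="normal_stride", scale=1.0):
    return GaitCondition(name=name, duration=duration, knots=(0.0, 1.0),
                         v_left=(v, v), v_right=(v, v),
                         stride_length_scale=scale)


class TestProtocol:
    def test_paper_preset_has_8_conditions(self):
        sched = make_protocol("paper")
        assert len(sched) == 8

    def test_sweep_condition_profile(self):
        sched = make_protocol("paper")
        sweep = sched[4]
        assert sweep.name == "speed_sweep"
        vl, _ = sweep.belt_speeds(np.array([0.0, sweep.duration / 2,
                                            sweep.duration]))
        assert vl == pytest.approx([0.1, 1.9, 0.1])

    def test_stop_go_alternates(self):
        sched = make_protocol("paper")
        sg = sched[7]
        assert sg.name == "stop_go"
        vl, _ = sg.belt_speeds(np.linspace(0, sg.duration, 200, endpoint=False))
        assert set(np.unique(vl)) == {0.0, 0.8}

    def test_explicit_list_identity(self):
        cond = _const_cond(0.8, duration=7.5)
        sched = make_protocol([cond])
        assert len(sched) == 1
        assert sched[0].duration == 7.5

    def test_unknown_preset_names_valid_ones(self):
        with pytest.raises(ValueError, match="paper"):
            make_protocol("bogus")

    def test_condition_validation(self):
        with pytest.raises(ValueError, match="belt speeds"):
            GaitCondition(name="normal_stride", duration=1.0, knots=(0.0, 1.0),
                          v_left=(2.5, 2.5), v_right=(2.5, 2.5))
        with pytest.raises(ValueError, match="unequal"):
            GaitCondition(name="asymmetric_left", duration=1.0,
                          knots=(0.0, 1.0), v_left=(0.8, 0.8),
                          v_right=(0.8, 0.8))


class TestJointTrajectories:
    def test_unit_cadence_sawtooth(self):
        """Cadence pinned to 1 stride/s: strikes 1 s apart, phase slope 1."""
        subject = SubjectParams(cadence_a=0.0, cadence_b=1.0, rng_seed=1)
        traj = joint_trajectories([_const_cond(0.8, duration=5.0)], subject)
        ev = traj["legs"]["r"]["events"]
        assert np.allclose(np.diff(ev), 1.0, atol=0.011)
        slope = np.diff(traj["legs"]["r"]["phi_unwrapped"]) * 100.0
        assert np.allclose(slope, 1.0, atol=1e-6)

    def test_phase_zero_at_events_within_one_sample(self, tiny_dataset):
        for session in tiny_dataset:
            for leg in ("r", "l"):
                phi = getattr(session.truth_phase, f"phi_{leg}")
                f = getattr(session.truth_phase, f"valid_{leg}")
                for t in session.truth_events[leg].times:
                    i = int(round(t * session.fs))
                    if i < phi.size and f[i]:
                        d = min(phi[i], 1.0 - phi[i])
                        # one sample at the local stride rate
                        assert d <= 0.011 * 1.2

    def test_asymmetric_stride_durations_follow_cadence_model(self):
        subject = SubjectParams(rng_seed=2)
        cond = GaitCondition(name="asymmetric_left", duration=60.0,
                             knots=(0.0, 1.0), v_left=(0.4, 0.4),
                             v_right=(0.8, 0.8), interp="step")
        traj = joint_trajectories([cond], subject)
        mean_r = np.mean(np.diff(traj["legs"]["r"]["events"]))
        mean_l = np.mean(np.diff(traj["legs"]["l"]["events"]))
        expected_r = 1.0 / subject.cadence(0.8)
        expected_l = 1.0 / subject.cadence(0.4)
        assert mean_r == pytest.approx(expected_r, rel=0.02)
        assert mean_l == pytest.approx(expected_l, rel=0.02)
        assert mean_l > mean_r

    def test_stop_interval_has_no_events_and_invalid_phase(self):
        subject = SubjectParams(rng_seed=3)
        cond = GaitCondition(name="stop_go", duration=30.0,
                             knots=(0.0, 1 / 3, 2 / 3),
                             v_left=(0.8, 0.0, 0.8), v_right=(0.8, 0.0, 0.8),
                             interp="step")
        traj = joint_trajectories([cond], subject)
        ev = traj["legs"]["r"]["events"]
        assert not np.any((ev > 10.5) & (ev < 19.5))
        t = traj["t"]
        stopped = (t > 10.01) & (t < 19.99)
        assert not traj["legs"]["r"]["valid"][stopped].any()
        # phase frozen during the stop
        phi = traj["legs"]["r"]["phi_unwrapped"]
        assert np.ptp(phi[stopped]) == pytest.approx(0.0, abs=1e-12)

    def test_stride_duration_monotone_in_speed(self):
        """Across speed plateaus, faster belts give shorter strides."""
        subject = SubjectParams(rng_seed=4)
        conds = [_const_cond(v, duration=25.0) for v in (0.2, 0.4, 0.8)]
        traj = joint_trajectories(conds, subject)
        ev = traj["legs"]["r"]["events"]
        means = []
        for lo, hi in ((0, 25), (25, 50), (50, 75)):
            sel = ev[(ev >= lo + 2) & (ev < hi - 0.5)]
            assert sel.size >= 10
            means.append(np.mean(np.diff(sel)))
        assert means[0] > means[1] > means[2]

    def test_left_right_interleaving(self):
        subject = SubjectParams(rng_seed=5)
        traj = joint_trajectories([_const_cond(0.8, duration=10.0)], subject)
        ev_r = traj["legs"]["r"]["events"]
        ev_l = traj["legs"]["l"]["events"]
        # every right-right interval contains exactly one left strike
        for a, b in zip(ev_r[:-1], ev_r[1:]):
            assert np.sum((ev_l > a) & (ev_l < b)) == 1

    def test_empty_schedule_raises(self):
        with pytest.raises(ValueError):
            joint_trajectories([], SubjectParams())


class TestSimulateImu:
    def test_stationary_statics(self):
        subject = SubjectParams(noise_std_accel=0.0, noise_std_gyro=0.0,
                                hip_coeffs=(0.0,) * 5,
                                knee_coeffs=(0.0,) * 6 + (0.72, 12.0))
        cond = GaitCondition(name="stop_go", duration=5.0, knots=(0.0, 1.0),
                             v_left=(0.0, 0.0), v_right=(0.0, 0.0),
                             interp="step")
        session = simulate_session([cond], subject)
        for name, stream in session.imu.items():
            assert np.allclose(stream.gyro, 0.0, atol=1e-12), name
            assert np.allclose(stream.accel[5:-5], [0.0, 0.0, 9.81],
                               atol=1e-6), name

    def test_quaternion_derivative_matches_gyro(self, quiet_session):
        """Finite differences of orientation agree with the reported rate."""
        stream = quiet_session.imu["shank_r"]
        dt = 1.0 / quiet_session.fs
        q = Rotation.from_quat(stream.quat[:, [1, 2, 3, 0]])
        # world-frame angular rate from consecutive orientations
        dq = q[1:] * q[:-1].inv()
        w_world = dq.as_rotvec() / dt
        w_sensor = q[:-1].inv().apply(w_world)
        mid = 0.5 * (stream.gyro[1:] + stream.gyro[:-1])
        err = np.abs(w_sensor - mid)
        assert np.percentile(err, 99) < 0.05  # O(dt) agreement

    def test_heel_z_minimum_at_heel_strikes(self, quiet_session):
        z = quiet_session.heel_z["r"]
        for t in quiet_session.truth_events["r"].times:
            i = int(round(t * quiet_session.fs))
            if 2 <= i < z.size - 2:
                assert z[i] <= z[i - 2] and z[i] <= z[i + 2]

    def test_heel_transient_energy(self):
        """The impact transient is present on the shank accelerometer and
        removing it changes the peak structure of shank a_z."""
        subject = SubjectParams(noise_std_accel=0.0, noise_std_gyro=0.0,
                                rng_seed=9)
        cond = _const_cond(0.8, duration=10.0)
        traj = joint_trajectories([cond], subject)
        rng = np.random.default_rng(0)
        with_tr, _ = simulate_imu(traj, subject, rng=rng, heel_transient_amp=4.0)
        rng = np.random.default_rng(0)
        without, _ = simulate_imu(traj, subject, rng=rng, heel_transient_amp=0.0)
        diff = with_tr["shank_r"].accel[:, 2] - without["shank_r"].accel[:, 2]
        for t in traj["legs"]["r"]["events"]:
            i = int(round(t * 100.0))
            seg = diff[i:i + 6]
            assert np.sum(seg**2) > 0.1
        from scipy.signal import find_peaks
        p_with, _ = find_peaks(with_tr["shank_r"].accel[:, 2], height=2.0)
        p_without, _ = find_peaks(without["shank_r"].accel[:, 2], height=2.0)
        assert len(p_with) != len(p_without)


class TestGenerateDataset:
    def test_subject_and_condition_counts(self):
        sessions = generate_dataset(2, "paper", 1, duration_scale=0.02)
        assert len(sessions) == 2
        assert len(sessions[0].schedule) == 8

    def test_determinism_under_fixed_seed(self):
        a = generate_dataset(2, "paper", 77, duration_scale=0.03)
        b = generate_dataset(2, "paper", 77, duration_scale=0.03)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.truth_events["r"].times,
                                  sb.truth_events["r"].times)
            ha = hashlib.sha256(sa.imu["shank_l"].accel.tobytes()).hexdigest()
            hb = hashlib.sha256(sb.imu["shank_l"].accel.tobytes()).hexdigest()
            assert ha == hb

    def test_different_seeds_differ(self):
        a = generate_dataset(1, "paper", 1, duration_scale=0.02)
        b = generate_dataset(1, "paper", 2, duration_scale=0.02)
        assert a[0].subject.thigh_length != b[0].subject.thigh_length

    def test_invalid_subject_count(self):
        with pytest.raises(ValueError):
            generate_dataset(0, "paper", 1)


class TestSubjectParams:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            SubjectParams(thigh_length=-0.1)
        with pytest.raises(ValueError):
            SubjectParams(sensor_offset_thigh=0.9, thigh_length=0.4)
        with pytest.raises(ValueError):
            SubjectParams(noise_std_accel=-1.0)
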