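"""Smoothing, landmark detection, and kinematic variables."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from artikin.core import (
    DerivedTraces,
    GestureLandmarks,
    InsufficientDataError,
    NoGestureError,
    ParameterError,
    Trajectory,
    UndefinedStiffnessError,
)
from artikin.gesture import GestureParams, simulate_ddk_train, simulate_gesture
from artikin.kinematics import (
    compute_kinematics,
    detect_landmarks,
    measure_cycles,
    smooth_and_differentiate,
)

from conftest import make_cell_spec, match_landmarks


def traj_from(values, sample_rate=250.0, sensor="test"):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) * 1000.0 / sample_rate
    return Trajectory(sensor, times, values, sample_rate)


class TestSmoothAndDifferentiate:
    def test_constant_trace_has_zero_derivatives(self):
        traces = smooth_and_differentiate(traj_from(np.full(100, 5.0)))
        assert np.allclose(traces.velocity, 0.0, atol=1e-9)
        assert np.allclose(traces.acceleration, 0.0, atol=1e-6)

    def test_sine_derivative_amplitude(self):
        """2 Hz sine at 20 Hz cutoff: velocity amplitude 2*pi*2*A within 2%."""
        a_mm, f = 3.0, 2.0
        t = np.arange(0, 3.0, 1 / 250.0)
        traj = traj_from(a_mm * np.sin(2 * np.pi * f * t))
        traces = smooth_and_differentiate(traj, cutoff=20.0)
        core = slice(50, -50)  # away from filter edge effects
        expected = 2 * np.pi * f * a_mm * 1000.0 / 1000.0  # mm/s
        assert np.max(np.abs(traces.velocity[core])) == pytest.approx(
            2 * np.pi * f * a_mm, rel=0.02)

    def test_noiseless_gesture_peak_velocity_within_2pct(self):
        p = GestureParams(5.0, 0.0, 20.0, 0.0, 600.0)
        traj = simulate_gesture(p, 250.0)
        traces = smooth_and_differentiate(traj)
        assert np.max(np.abs(traces.velocity)) == pytest.approx(
            5.0 * 20.0 / np.e, rel=0.02)

    def test_parameter_errors(self):
        with pytest.raises(InsufficientDataError):
            smooth_and_differentiate(traj_from(np.zeros(5)))
        with pytest.raises(ParameterError):
            smooth_and_differentiate(traj_from(np.zeros(100)), cutoff=125.0)
        with pytest.raises(ParameterError):
            smooth_and_differentiate(traj_from(np.zeros(100)), cutoff=-1.0)


class TestDetectLandmarks:
    def test_flat_trace_is_no_gesture(self):
        traces = smooth_and_differentiate(traj_from(np.full(200, 2.0)))
        with pytest.raises(NoGestureError):
            detect_landmarks(traces, (0.0, 790.0))

    def test_noiseless_train_recovery_within_one_sample(self):
        """All three landmarks within 4 ms (1 sample at 250 Hz) of truth."""
        spec = make_cell_spec("control", "pa", noise_sd=0.0)
        traj, truth, cycles = simulate_ddk_train(spec)
        measured = measure_cycles(traj, cycles[3:])
        for gt, lm, _ in match_landmarks(truth, cycles[3:], measured):
            assert abs(lm.onset_ms - gt.onset_ms) <= 4.0
            assert abs(lm.pvel_ms - gt.pvel_ms) <= 4.0
            assert abs(lm.target_ms - gt.target_ms) <= 4.0

    def test_noisy_peak_velocity_median_error_within_one_sample(self):
        """0.1 mm position noise, 100 cycles: median |pvel error| <= 4 ms."""
        spec = make_cell_spec("control", "pa", noise_sd=0.1, n_cycles=103,
                              seed=5)
        traj, truth, cycles = simulate_ddk_train(spec)
        measured = measure_cycles(traj, cycles[3:])
        errs = [abs(lm.pvel_ms - gt.pvel_ms)
                for gt, lm, _ in match_landmarks(truth, cycles[3:], measured)]
        assert len(errs) == 100
        assert np.median(errs) <= 4.0

    def test_translation_and_sign_invariance(self):
        """Flipping raising/lowering flips nothing but positions."""
        spec = make_cell_spec("control", "ta", noise_sd=0.0)
        traj, _, cycles = simulate_ddk_train(spec)
        flipped = Trajectory(traj.sensor, traj.times, 10.0 - traj.positions,
                             traj.sample_rate)
        m1 = measure_cycles(traj, cycles[3:])
        m2 = measure_cycles(flipped, cycles[3:])
        for (lm1, k1), (lm2, k2) in zip(m1, m2):
            assert lm1.onset_ms == pytest.approx(lm2.onset_ms, abs=1e-9)
            assert lm1.pvel_ms == pytest.approx(lm2.pvel_ms, abs=1e-9)
            assert lm1.target_ms == pytest.approx(lm2.target_ms, abs=1e-9)
            assert lm1.onset_pos == pytest.approx(10.0 - lm2.onset_pos)
            assert k1.displacement_mm == pytest.approx(k2.displacement_mm)
            assert k1.stiffness_per_s == pytest.approx(k2.stiffness_per_s)

    def test_subthreshold_movement_rejected(self):
        p = GestureParams(0.05, 0.0, 20.0, 0.0, 600.0)  # 50 micron movement
        traces = smooth_and_differentiate(simulate_gesture(p, 250.0))
        with pytest.raises(NoGestureError, match="noise floor"):
            detect_landmarks(traces, (0.0, 800.0))


class TestComputeKinematics:
    def test_definitional_arithmetic(self):
        """Onset (0 ms, 0 mm), peak 100 mm/s at 30 ms, target (80 ms, 5 mm)."""
        times = np.array([0.0, 30.0, 80.0])
        traces = DerivedTraces(
            times=times,
            position=np.array([0.0, 2.5, 5.0]),
            velocity=np.array([0.0, 100.0, 0.0]),
            acceleration=np.zeros(3),
            sample_rate=250.0,
        )
        lm = GestureLandmarks(0.0, 30.0, 80.0, 0.0, 5.0)
        kin = compute_kinematics(traces, lm)
        assert kin.accel_phase_ms == 30.0
        assert kin.decel_phase_ms == 50.0
        assert kin.displacement_mm == 5.0
        assert kin.peak_velocity_mm_s == 100.0
        assert kin.stiffness_per_s == 20.0

    def test_phase_partition_is_exact(self):
        spec = make_cell_spec("OFF", "pa", noise_sd=0.1, seed=3)
        traj, _, cycles = simulate_ddk_train(spec)
        for lm, kin in measure_cycles(traj, cycles[3:]):
            assert kin.accel_phase_ms + kin.decel_phase_ms == pytest.approx(
                lm.target_ms - lm.onset_ms, abs=1e-9)

    def test_isolated_gesture_stiffness_near_omega_over_e(self):
        """For omega = 20/s the measured index is ~20/e (threshold-dependent)."""
        p = GestureParams(5.0, 0.0, 20.0, 100.0, 700.0)
        traces = smooth_and_differentiate(simulate_gesture(p, 250.0))
        lm = detect_landmarks(traces, (0.0, 880.0))
        kin = compute_kinematics(traces, lm)
        assert kin.stiffness_per_s == pytest.approx(20.0 / np.e, rel=0.05)

    def test_zero_displacement_errors(self):
        traces = DerivedTraces(
            times=np.array([0.0, 30.0, 80.0]),
            position=np.array([1.0, 1.0, 1.0]),
            velocity=np.array([0.0, 50.0, 0.0]),
            acceleration=np.zeros(3),
            sample_rate=250.0,
        )
        lm = GestureLandmarks(0.0, 30.0, 80.0, 1.0, 1.0)
        with pytest.raises(UndefinedStiffnessError):
            compute_kinematics(traces, lm)


class TestParameterRecovery:
    def test_measured_stiffness_monotone_in_omega(self):
        """The stiffness index strictly increases in omega at fixed amplitude."""
        measured = []
        for omega in (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0):
            p = GestureParams(5.0, 0.0, omega, 100.0, 100.0 + 12000.0 / omega)
            traces = smooth_and_differentiate(simulate_gesture(p, 250.0))
            lm = detect_landmarks(traces, (0.0, traces.times[-1]))
            measured.append(compute_kinematics(traces, lm).stiffness_per_s)
        assert np.all(np.diff(measured) > 0)

    def test_rank_correlation_with_true_omega(self):
        """Spearman(true omega, measured stiffness) >= 0.9 on 100 noisy gestures."""
        rng = np.random.default_rng(17)
        true_omega, stiffness = [], []
        for _ in range(100):
            omega = rng.uniform(10.0, 40.0)
            amp = rng.uniform(3.0, 10.0)
            p = GestureParams(amp, 0.0, omega, 50.0, 50.0 + 9000.0 / omega)
            traj = simulate_gesture(p, 250.0)
            noisy = Trajectory(
                traj.sensor, traj.times,
                traj.positions + rng.normal(0.0, 0.1, traj.times.size),
                traj.sample_rate,
            )
            traces = smooth_and_differentiate(noisy)
            lm = detect_landmarks(traces, (0.0, traces.times[-1]))
            kin = compute_kinematics(traces, lm)
            true_omega.append(omega)
            stiffness.append(kin.stiffness_per_s)
        rho = spearmanr(true_omega, stiffness).statistic
        assert rho >= 0.9
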