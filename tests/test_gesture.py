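"""Mass-spring gesture model: closed form, modifications, train composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from artikin.core import ParameterError, TruncationWarning
from artikin.gesture import (
    DDKSpec,
    GestureParams,
    apply_modification,
    simulate_ddk_train,
    simulate_gesture,
)

from conftest import make_cell_spec


def isolated(amp=5.0, omega=20.0, onset=0.0, offset=600.0, rest=0.0):
    return GestureParams(rest + amp, rest, omega, onset, offset)


class TestSimulateGesture:
    def test_matches_numerical_ode_integration(self):
        """Closed form equals Runge-Kutta integration of the attractor ODE."""
        p = isolated(amp=5.0, omega=20.0, offset=500.0)
        traj = simulate_gesture(p, sample_rate=250.0)
        active = traj.times <= p.activation_offset
        t_eval = traj.times[active] / 1000.0
        sol = solve_ivp(
            lambda t, s: [s[1], -p.natural_freq**2 * (s[0] - p.target_pos)
                          - 2 * p.natural_freq * s[1]],
            (0.0, t_eval[-1]), [0.0, 0.0], t_eval=t_eval,
            rtol=1e-12, atol=1e-12,
        )
        assert np.max(np.abs(sol.y[0] - traj.positions[active])) <= 1e-6

    def test_attractor_fixed_point(self):
        """Run to t >> 1/omega: the articulator settles on the target."""
        traj = simulate_gesture(isolated(amp=5.0, omega=20.0, offset=800.0),
                                sample_rate=250.0)
        assert traj.positions[-1] == pytest.approx(5.0, abs=1e-3)

    def test_peak_velocity_closed_form(self):
        """v_peak = |x0-T| * omega / e at t = 1/omega after onset."""
        traj = simulate_gesture(isolated(amp=5.0, omega=20.0), 1000.0)
        vel = np.gradient(traj.positions, 1e-3)
        i = np.argmax(vel)
        assert vel[i] == pytest.approx(5.0 * 20.0 / np.e, rel=1e-3)  # 36.79
        assert traj.times[i] == pytest.approx(50.0, abs=1.0)

    def test_amplitude_scales_velocity_not_timing(self):
        """Doubling |T-x0| doubles v_peak but leaves time-to-peak at 1/omega."""
        v = {}
        for amp in (5.0, 10.0):
            traj = simulate_gesture(isolated(amp=amp, omega=20.0), 1000.0)
            vel = np.gradient(traj.positions, 1e-3)
            v[amp] = (vel.max(), traj.times[np.argmax(vel)])
        assert v[10.0][0] == pytest.approx(2 * v[5.0][0], rel=1e-6)
        assert v[10.0][1] == v[5.0][1]

    def test_monotone_approach_and_hold(self):
        p = isolated(amp=4.0, omega=15.0, onset=100.0, offset=500.0)
        traj = simulate_gesture(p, 250.0, duration_ms=700.0)
        pre = traj.positions[traj.times < 100.0]
        assert np.all(pre == 0.0)
        active = traj.positions[(traj.times >= 100.0) & (traj.times <= 500.0)]
        assert np.all(np.diff(active) >= -1e-12)
        held = traj.positions[traj.times > 500.0]
        assert np.allclose(held, held[0])

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            GestureParams(5.0, 0.0, -1.0, 0.0, 100.0)
        with pytest.raises(ParameterError):
            GestureParams(5.0, 0.0, 10.0, 100.0, 100.0)
        with pytest.raises(ParameterError):
            simulate_gesture(isolated(), sample_rate=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        omega=st.floats(5.0, 60.0),
        amp=st.floats(0.5, 20.0),
    )
    def test_velocity_scaling_invariants(self, omega, amp):
        """v_peak / amplitude = omega / e and time-to-peak = 1/omega."""
        traj = simulate_gesture(
            isolated(amp=amp, omega=omega, offset=8000.0 / omega), 2000.0
        )
        vel = np.gradient(traj.positions, 0.5e-3)
        assert vel.max() / amp == pytest.approx(omega / np.e, rel=5e-3)
        assert traj.times[np.argmax(vel)] == pytest.approx(1000.0 / omega,
                                                           rel=2e-2)


class TestApplyModification:
    def spec(self):
        return make_cell_spec("control", "pa")

    @pytest.mark.parametrize("mode", ["target", "stiffness", "rescaling",
                                      "phasing"])
    def test_factor_one_is_identity(self, mode):
        assert apply_modification(self.spec(), mode, 1.0) == self.spec()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError, match="unknown modification"):
            apply_modification(self.spec(), "elasticity", 2.0)
        with pytest.raises(ParameterError):
            apply_modification(self.spec(), "target", -1.0)

    def test_target_scales_amplitude_only(self):
        mod = apply_modification(self.spec(), "target", 0.5)
        assert mod.closing_params.amplitude == pytest.approx(
            0.5 * self.spec().closing_params.amplitude)
        assert mod.closing_params.natural_freq == \
            self.spec().closing_params.natural_freq

    def test_stiffness_scales_omega_squared(self):
        mod = apply_modification(self.spec(), "stiffness", 4.0)
        assert mod.closing_params.natural_freq == pytest.approx(
            2.0 * self.spec().closing_params.natural_freq)

    def test_rescaling_preserves_predicted_peak_velocity(self):
        base = self.spec()
        mod = apply_modification(base, "rescaling", 0.5)
        assert mod.closing_params.amplitude == pytest.approx(
            0.5 * base.closing_params.amplitude)
        assert mod.closing_params.peak_velocity() == pytest.approx(
            base.closing_params.peak_velocity(), rel=1e-12)

    def test_phasing_multiplies_and_clamps(self):
        assert apply_modification(self.spec(), "phasing", 0.6).phasing == 0.6
        assert apply_modification(self.spec(), "phasing", 5.0).phasing == 1.0


class TestSimulateTrain:
    def test_periodic_steady_state_amplitudes(self):
        """Noiseless, phasing 1: peak-to-peak amplitudes equal within 1%."""
        spec = make_cell_spec("control", "pa", noise_sd=0.0)
        traj, _, cycles = simulate_ddk_train(spec)
        p2p = []
        for cyc in cycles[3:]:
            m = (traj.times >= cyc.cycle_start_ms) & \
                (traj.times <= cyc.cycle_end_ms)
            p2p.append(np.ptp(traj.positions[m]))
        assert max(p2p) / min(p2p) - 1 < 0.01

    def test_deterministic_under_seed(self):
        spec = make_cell_spec("OFF", "ta", noise_sd=0.1, seed=7,
                              cycle_jitter_sd=0.05)
        a = simulate_ddk_train(spec)
        b = simulate_ddk_train(spec)
        assert np.array_equal(a[0].positions, b[0].positions)
        assert a[1] == b[1]
        assert [c.voiced_spans for c in a[2]] == [c.voiced_spans for c in b[2]]

    def test_counts_and_annotation_layout(self):
        spec = make_cell_spec("control", "ka", n_cycles=13)
        traj, landmarks, cycles = simulate_ddk_train(spec)
        assert len(landmarks) == 13
        assert len(cycles) == 13
        for cyc in cycles:
            assert cyc.closure_start_ms == cyc.cycle_start_ms
            assert cyc.vowel_end_ms == cyc.cycle_end_ms
            assert cyc.closure_end_ms == cyc.vowel_start_ms
            for s, e in cyc.voiced_spans:
                assert cyc.cycle_start_ms - 1e-9 <= s < e <= \
                    cyc.cycle_end_ms + 1e-9

    def test_ground_truth_ordering(self):
        _, landmarks, _ = simulate_ddk_train(make_cell_spec("ON", "ka"))
        for lm in landmarks:
            assert lm.onset_ms < lm.pvel_ms < lm.target_ms

    def test_truncation_regime_warns_not_errors(self):
        spec = make_cell_spec("control", "pa")
        # omega low for this period: target approached < 95% before next onset
        with pytest.warns(TruncationWarning):
            simulate_ddk_train(spec)

    def test_short_cycle_period_rejected(self):
        close = GestureParams(5.0, 0.0, 20.0, 0.0, 200.0)
        open_ = GestureParams(0.0, 5.0, 20.0, 0.0, 100.0)
        with pytest.raises(ParameterError):
            DDKSpec(syllable="pa", n_cycles=13, cycle_period=150.0,
                    closing_params=close, opening_params=open_)

    def test_invalid_spec_fields(self):
        close = GestureParams(5.0, 0.0, 20.0, 0.0, 80.0)
        open_ = GestureParams(0.0, 5.0, 20.0, 0.0, 80.0)
        with pytest.raises(ParameterError):
            DDKSpec(syllable="ba", n_cycles=13, cycle_period=200.0,
                    closing_params=close, opening_params=open_)
        with pytest.raises(ParameterError):
            DDKSpec(syllable="pa", n_cycles=13, cycle_period=200.0,
                    closing_params=close, opening_params=open_, phasing=0.0)
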