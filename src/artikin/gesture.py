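"""Critically damped mass-spring model of articulatory gestures.

A gesture is a goal-directed movement of an articulator modelled as a
point attractor: a unit mass on a critically damped spring pulled towards a
target position T,

    x'' = -omega^2 (x - T) - 2 omega x'

where ``omega`` (1/s) is the natural frequency; the abstract spring
stiffness is k = omega^2.  For initial state (x0, v0) at activation onset
the closed-form solution is

    x(t) = T + (A + B t) exp(-omega t),   A = x0 - T,  B = v0 + omega A
    v(t) = (B - omega (A + B t)) exp(-omega t)
    a(t) = (omega^2 (A + B t) - 2 omega B) exp(-omega t)

Starting from rest the approach to T is monotone, the peak velocity is
|x0 - T| * omega / e, and the time to peak velocity is 1/omega independent
of the movement amplitude — the kinematic signatures that make omega a
useful control parameter for the relative speed of a movement.

DDK (diadochokinesis) syllable trains are composed from alternating closing
and opening gestures.  At each new gesture onset the state (x, v) is
carried over and the attractor switches, so that an early-timed next
gesture truncates the preceding movement — especially its deceleration
phase — while leaving the peak velocity essentially untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .core import (
    GestureLandmarks,
    ParameterError,
    SyllableCycle,
    Trajectory,
    TruncationWarning,
)

__all__ = [
    "GestureParams",
    "AnnotationModel",
    "DDKSpec",
    "SENSOR_FOR_SYLLABLE",
    "simulate_gesture",
    "apply_modification",
    "simulate_ddk_train",
]

#: Articulator channel measured for each place of articulation.
SENSOR_FOR_SYLLABLE = {"pa": "lower-lip", "ta": "tongue-tip", "ka": "tongue-dorsum"}

MODIFICATION_MODES = ("target", "stiffness", "rescaling", "phasing")


@dataclass(frozen=True)
class GestureParams:
    """Control parameters of one gesture.

    Parameters
    ----------
    target_pos : float
        Attractor position T in mm.
    rest_pos : float
        Start position x0 in mm (for an isolated gesture starting from rest).
    natural_freq : float
        omega in 1/s; the abstract stiffness is omega**2.
    activation_onset, activation_offset : float
        Activation interval in ms; the attractor acts only while active.
    """

    target_pos: float
    rest_pos: float
    natural_freq: float
    activation_onset: float
    activation_offset: float

    def __post_init__(self) -> None:
        if not self.natural_freq > 0:
            raise ParameterError("natural_freq must be positive")
        if not self.activation_offset > self.activation_onset:
            raise ParameterError("activation_offset must exceed activation_onset")

    @property
    def amplitude(self) -> float:
        """|target - rest| in mm."""
        return abs(self.target_pos - self.rest_pos)

    @property
    def activation_ms(self) -> float:
        return self.activation_offset - self.activation_onset

    def peak_velocity(self) -> float:
        """Predicted peak velocity |x0-T| * omega / e (mm/s), from rest."""
        return self.amplitude * self.natural_freq / np.e


@dataclass(frozen=True)
class AnnotationModel:
    """Generative model for the annotation tiers of a synthetic train.

    The closure occupies ``closure_frac`` of each cycle (constriction first,
    vowel after); the vowel is fully voiced.  With probability
    ``p_voice_closure`` voicing carries on into the closure for a span drawn
    uniformly from ``voiced_span_ms`` (always > 20 ms), otherwise only a
    short coarticulatory remnant drawn from ``coart_span_ms`` (always
    <= 20 ms, attributable to the preceding vowel).  ``p_frication`` is the
    probability of the binary frication-during-closure label.
    """

    closure_frac: float = 0.5
    p_voice_closure: float = 0.4
    p_frication: float = 0.2
    voiced_span_ms: tuple[float, float] = (25.0, 45.0)
    coart_span_ms: tuple[float, float] = (5.0, 15.0)

    def __post_init__(self) -> None:
        for name in ("p_voice_closure", "p_frication"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 < self.closure_frac < 1.0:
            raise ParameterError("closure_frac must lie in (0, 1)")


@dataclass(frozen=True)
class DDKSpec:
    """Specification of one DDK syllable train.

    Closing gesture onsets sit on the fixed ``cycle_period`` grid (the
    controlled repetition rate).  ``phasing`` is the relative onset of the
    opening gesture within the closing gesture's activation: the opening
    gesture starts at ``phasing * closing activation`` after the closing
    onset, so values < 1 produce overlap and truncate the closing movement.
    """

    syllable: str
    n_cycles: int
    cycle_period: float
    closing_params: GestureParams
    opening_params: GestureParams
    phasing: float = 1.0
    noise_sd: float = 0.0
    sample_rate: float = 250.0
    seed: int = 0
    annotation: AnnotationModel = field(default_factory=AnnotationModel)
    #: lognormal SD (log scale) of per-cycle period jitter; each cycle's
    #: activation durations scale with its period.  0 = strictly periodic.
    cycle_jitter_sd: float = 0.0
    #: lognormal SDs of per-cycle movement amplitude and natural frequency
    amplitude_jitter_sd: float = 0.0
    freq_jitter_sd: float = 0.0
    #: floor on each cycle's predicted peak velocity (mm/s); jittered cycles
    #: falling below it have their amplitude raised to meet it.  0 disables.
    min_cycle_peak_velocity: float = 0.0
    #: minimum fraction of the opening movement completed before the next
    #: closing onset; slow jittered openings are sped up to meet it.
    #: 0 disables.
    min_opening_recovery: float = 0.0
    #: floor on each cycle's movement amplitude (mm); a stop closure needs
    #: a minimum excursion to occlude the tract.  0 disables.
    min_cycle_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.syllable not in SENSOR_FOR_SYLLABLE:
            raise ParameterError(
                f"syllable must be one of {sorted(SENSOR_FOR_SYLLABLE)}, "
                f"got {self.syllable!r}"
            )
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if not 0.0 < self.phasing <= 1.0:
            raise ParameterError("phasing must lie in (0, 1]")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        for name in ("cycle_jitter_sd", "amplitude_jitter_sd", "freq_jitter_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not self.cycle_period > 0:
            raise ParameterError("cycle_period must be positive")
        trunc = self.phasing * self.closing_params.activation_ms
        if trunc >= self.cycle_period:
            raise ParameterError(
                "opening onset (phasing * closing activation) must fall "
                "within the cycle period"
            )


# ---------------------------------------------------------------------------
# closed-form segment algebra


def _coeffs(x0: float, v0: float, target: float, omega: float):
    a = x0 - target
    return a, v0 + omega * a


def _eval_xva(t_s, x0, v0, target, omega):
    """Closed-form position/velocity/acceleration t_s seconds after onset."""
    a, b = _coeffs(x0, v0, target, omega)
    decay = np.exp(-omega * np.asarray(t_s, dtype=float))
    lin = a + b * np.asarray(t_s, dtype=float)
    x = target + lin * decay
    v = (b - omega * lin) * decay
    acc = (omega**2 * lin - 2.0 * omega * b) * decay
    return x, v, acc


class _PiecewiseTrain:
    """Piecewise closed-form evaluation of a gesture sequence.

    Segments are (t_start_ms, t_end_ms, target, omega) with state carried
    across boundaries; ``target is None`` denotes a hold (frozen position).
    """

    def __init__(self, segments, x_init: float):
        self.starts = np.array([s[0] for s in segments], dtype=float)
        self.ends = np.array([s[1] for s in segments], dtype=float)
        self.segments = segments
        # propagate state through segment boundaries
        self.states = []
        x, v = x_init, 0.0
        for (t0, t1, target, omega) in segments:
            self.states.append((x, v))
            if target is None:
                v = 0.0
            else:
                dt = (t1 - t0) / 1000.0
                x, v, _ = _eval_xva(dt, x, v, target, omega)
                x, v = float(x), float(v)

    def __call__(self, t_ms):
        """Vectorised (x, v, a) at absolute times in ms."""
        t_ms = np.atleast_1d(np.asarray(t_ms, dtype=float))
        idx = np.clip(np.searchsorted(self.starts, t_ms, side="right") - 1, 0, None)
        x = np.empty_like(t_ms)
        v = np.empty_like(t_ms)
        acc = np.empty_like(t_ms)
        for i in np.unique(idx):
            sel = idx == i
            t0, _t1, target, omega = self.segments[i]
            x0, v0 = self.states[i]
            if target is None:
                x[sel], v[sel], acc[sel] = x0, 0.0, 0.0
            else:
                dt = (t_ms[sel] - t0) / 1000.0
                x[sel], v[sel], acc[sel] = _eval_xva(dt, x0, v0, target, omega)
        return x, v, acc

    def velocity(self, t_ms: float) -> float:
        return float(self(t_ms)[1][0])


# ---------------------------------------------------------------------------
# operations


def simulate_gesture(
    params: GestureParams,
    sample_rate: float = 250.0,
    duration_ms: float | None = None,
) -> Trajectory:
    """Simulate one isolated gesture starting from rest.

    The articulator holds ``rest_pos`` before activation onset, follows the
    critically damped point-attractor dynamics during the activation
    interval, and holds its achieved position afterwards.

    Parameters
    ----------
    params
        Gesture control parameters; ``natural_freq`` must be positive.
    sample_rate
        Output grid in Hz.
    duration_ms
        Total simulated time; defaults to the activation offset plus five
        time constants (5/omega), which covers the approach to the target.
    """
    if sample_rate <= 0:
        raise ParameterError("sample_rate must be positive")
    if duration_ms is None:
        duration_ms = params.activation_offset + 5000.0 / params.natural_freq
    if duration_ms < params.activation_offset:
        raise ParameterError("grid must cover the activation interval")
    step = 1000.0 / sample_rate
    times = np.arange(0.0, duration_ms + step / 2, step)
    segments = []
    if params.activation_onset > 0:
        segments.append((0.0, params.activation_onset, None, None))
    segments.append(
        (params.activation_onset, params.activation_offset,
         params.target_pos, params.natural_freq)
    )
    segments.append((params.activation_offset, times[-1], None, None))
    train = _PiecewiseTrain(segments, params.rest_pos)
    positions = train(times)[0]
    return Trajectory("gesture", times, positions, sample_rate)


def apply_modification(spec: DDKSpec, mode: str, factor: float) -> DDKSpec:
    """Return a new train spec with one control parameter modified.

    ``target`` scales the closing movement amplitude |T - x0| by ``factor``
    (smaller targets give proportionally slower but not shorter movements);
    ``stiffness`` scales the abstract stiffness omega^2 by ``factor``
    (faster and shorter movements); ``rescaling`` jointly scales amplitude
    by ``factor`` and omega by 1/``factor`` so the predicted peak velocity
    |x0 - T| * omega / e is unchanged; ``phasing`` multiplies the phasing
    fraction by ``factor`` (clamped to (0, 1]), with values < 1 truncating
    the closing gesture.
    """
    if factor <= 0:
        raise ParameterError("factor must be positive")
    if mode not in MODIFICATION_MODES:
        raise ParameterError(
            f"unknown modification mode {mode!r}; expected one of "
            f"{MODIFICATION_MODES}"
        )
    close, open_ = spec.closing_params, spec.opening_params

    def _scale_amplitude(p: GestureParams, f: float) -> GestureParams:
        return replace(p, target_pos=p.rest_pos + f * (p.target_pos - p.rest_pos))

    def _scale_omega(p: GestureParams, f: float) -> GestureParams:
        return replace(p, natural_freq=p.natural_freq * f)

    if mode == "target":
        close = _scale_amplitude(close, factor)
        open_ = replace(open_, rest_pos=close.target_pos)
    elif mode == "stiffness":
        f = float(np.sqrt(factor))  # omega^2 scales by `factor`
        close, open_ = _scale_omega(close, f), _scale_omega(open_, f)
    elif mode == "rescaling":
        close = _scale_amplitude(close, factor)
        open_ = replace(open_, rest_pos=close.target_pos)
        close, open_ = _scale_omega(close, 1.0 / factor), _scale_omega(open_, 1.0 / factor)
    elif mode == "phasing":
        return replace(spec, phasing=min(1.0, spec.phasing * factor))
    return replace(spec, closing_params=close, opening_params=open_)


def _refine_root(fun, lo: float, hi: float) -> float:
    flo, fhi = fun(lo), fun(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:  # no sign change; fall back to midpoint
        return 0.5 * (lo + hi)
    return float(brentq(fun, lo, hi, xtol=1e-9))


def _ground_truth_landmarks(train, t_close, t_open, close_params, fine_step):
    """Analytic landmarks for one closing gesture.

    onset: the velocity zero-crossing at the movement turnaround (or the
    activation onset itself when the articulator is already at rest or
    moving towards the target); peak velocity: the interior acceleration
    zero-crossing; target: the first velocity zero-crossing after the peak
    (created by truncation or the following opening gesture).
    """
    d = 1.0 if close_params.target_pos >= close_params.rest_pos else -1.0
    v_on = train.velocity(t_close)
    if d * v_on >= -1e-12:
        onset = t_close
    else:
        onset = _refine_root(lambda t: train.velocity(t), t_close, t_open)

    # peak velocity: acceleration root between onset and truncation
    grid = np.arange(onset, t_open, fine_step)
    if grid.size < 2:
        grid = np.array([onset, t_open])
    acc = train(grid)[2]
    sign = np.sign(acc)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    accel_root = lambda t: train(t)[2][0]
    if flips.size:
        vel = train(grid)[1]
        best = flips[np.argmax(d * 0.5 * (vel[flips] + vel[flips + 1]))]
        pvel = _refine_root(accel_root, grid[best], grid[best + 1])
    else:  # peak at truncation boundary
        pvel = float(grid[np.argmax(d * train(grid)[1])])

    # target: first velocity zero after pvel (search across the truncation)
    t_hi = t_open + max(4 * fine_step, 0.6 * (t_open - t_close))
    grid = np.arange(pvel + fine_step, t_hi, fine_step)
    vel = train(grid)[1]
    below = np.nonzero(d * vel <= 0)[0]
    if below.size:
        j = below[0]
        lo = grid[j - 1] if j > 0 else pvel
        target = _refine_root(lambda t: train.velocity(t), lo, grid[j])
    else:
        target = float(grid[-1])
    x = train(np.array([onset, target]))[0]
    return GestureLandmarks(onset, pvel, target, float(x[0]), float(x[1]))


def simulate_ddk_train(
    spec: DDKSpec,
) -> tuple[Trajectory, list[GestureLandmarks], list[SyllableCycle]]:
    """Simulate a DDK train with ground-truth landmarks and annotation tiers.

    Returns the sampled trajectory (with additive Gaussian position noise of
    ``spec.noise_sd`` mm), one ground-truth landmark set per closing gesture
    of the ``n_cycles`` annotated cycles, and the annotation tiers.  The
    trajectory covers ``n_cycles + 1`` closing gestures so that the last
    annotated cycle has a following constriction to end on.

    The same ``spec`` (including its seed) always yields bit-identical
    output.
    """
    close, open_ = spec.closing_params, spec.opening_params
    period = spec.cycle_period
    d_close = close.activation_ms
    t_trunc_s = spec.phasing * d_close / 1000.0
    resid = (1.0 + close.natural_freq * t_trunc_s) * np.exp(
        -close.natural_freq * t_trunc_s
    )
    if resid > 0.05:
        warnings.warn(
            f"cycle period {period:.0f} ms is short for omega = "
            f"{close.natural_freq:.1f}/s: the closing target is only "
            f"approached to {100 * (1 - resid):.0f}% before the next gesture "
            "onset (truncation regime)",
            TruncationWarning,
            stacklevel=2,
        )

    n_gestures = spec.n_cycles + 1
    rng = np.random.default_rng(spec.seed)

    def jitter(sd: float) -> np.ndarray:
        # winsorised at +/- 2 SD: adjacent syllable cycles do not jump by
        # 3-sigma tempo or amplitude steps in real productions
        if sd == 0.0:
            return np.ones(n_gestures)
        z = np.clip(rng.standard_normal(n_gestures), -2.0, 2.0)
        return np.exp(-0.5 * sd * sd + sd * z)

    m_period = jitter(spec.cycle_jitter_sd)
    m_amp = jitter(spec.amplitude_jitter_sd)
    m_freq = jitter(spec.freq_jitter_sd)

    if spec.min_cycle_peak_velocity > 0.0 and close.amplitude > 0.0:
        # a produced syllable implies a measurable movement: raise the
        # amplitude of pathologically slow jittered cycles to the floor.
        # The attainable peak accounts for truncation before 1/omega:
        # v_max = amp * omega / e * min(1, u * e^(1-u)), u = omega * t_trunc
        omega_k = close.natural_freq * m_freq
        u = omega_k * (spec.phasing * d_close * m_period) / 1000.0
        # truncation only caps the peak when it falls before 1/omega (u < 1)
        trunc_factor = np.where(u >= 1.0, 1.0, u * np.exp(1.0 - u))
        pv = close.amplitude * m_amp * omega_k / np.e * trunc_factor
        m_amp = m_amp * np.maximum(1.0, spec.min_cycle_peak_velocity / pv)
    if spec.min_cycle_amplitude > 0.0 and close.amplitude > 0.0:
        m_amp = np.maximum(m_amp, spec.min_cycle_amplitude / close.amplitude)

    segments = []
    closings = []  # (t_close, t_open, params) per gesture
    t_close = 0.0
    sign = 1.0 if close.target_pos >= close.rest_pos else -1.0
    for k in range(n_gestures):
        period_k = period * m_period[k]
        amp_k = close.amplitude * m_amp[k]
        omega_k = close.natural_freq * m_freq[k]
        target_k = close.rest_pos + sign * amp_k
        t_open = t_close + spec.phasing * d_close * m_period[k]
        t_next = t_close + period_k
        t_open_end = min(t_open + open_.activation_ms * m_period[k], t_next)
        omega_open = open_.natural_freq * m_freq[k]
        if spec.min_opening_recovery > 0.0 and t_next > t_open:
            # the opening must bring the articulator back towards rest
            # before the next closing, or subsequent movements collapse;
            # raise this cycle's opening frequency until the critically
            # damped residual (1 + u) e^-u at the next onset is small enough
            resid_allowed = 1.0 - spec.min_opening_recovery
            u_needed = float(
                brentq(lambda u: (1.0 + u) * np.exp(-u) - resid_allowed,
                       1e-6, 50.0)
            )
            omega_open = max(omega_open,
                             1000.0 * u_needed / (t_next - t_open))
        segments.append((t_close, t_open, target_k, omega_k))
        segments.append((t_open, t_open_end, open_.target_pos, omega_open))
        if t_open_end < t_next:
            segments.append((t_open_end, t_next, None, None))
        closings.append((t_close, t_open, replace(
            close, target_pos=target_k, natural_freq=omega_k)))
        t_close = t_next
    total = t_close
    train = _PiecewiseTrain(segments, close.rest_pos)

    step = 1000.0 / spec.sample_rate
    times = np.arange(0.0, total + step / 2, step)
    positions = train(times)[0]
    if spec.noise_sd > 0:
        positions = positions + rng.normal(0.0, spec.noise_sd, size=times.size)

    fine = min(1.0, step / 4.0)
    landmarks = []
    targets = []
    for k, (t_c, t_o, params_k) in enumerate(closings):
        lm = _ground_truth_landmarks(train, t_c, t_o, params_k, fine)
        targets.append(lm.target_ms)
        if k < spec.n_cycles:
            landmarks.append(lm)

    ann = spec.annotation
    cycles = []
    for k in range(spec.n_cycles):
        c_start, c_end = targets[k], targets[k + 1]
        dur = c_end - c_start
        d_clo = ann.closure_frac * dur
        closure = (c_start, c_start + d_clo)
        vowel = (c_start + d_clo, c_end)
        spans = [vowel]
        if rng.random() < ann.p_voice_closure:
            lo, hi = ann.voiced_span_ms
        else:
            lo, hi = ann.coart_span_ms
        span_len = min(rng.uniform(lo, hi), d_clo - 1e-6)
        spans.insert(0, (c_start, c_start + span_len))
        frication = bool(rng.random() < ann.p_frication)
        cycles.append(
            SyllableCycle(
                cycle_index=k + 1,
                cycle_start_ms=c_start,
                cycle_end_ms=c_end,
                closure_start_ms=closure[0],
                closure_end_ms=closure[1],
                vowel_start_ms=vowel[0],
                vowel_end_ms=vowel[1],
                voiced_spans=spans,
                frication_flag=frication,
            )
        )

    traj = Trajectory(SENSOR_FOR_SYLLABLE[spec.syllable], times, positions,
                      spec.sample_rate)
    return traj, landmarks, cycles
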