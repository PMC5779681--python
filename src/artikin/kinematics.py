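"""Signal conditioning, gestural landmark detection, and kinematic measures.

The measurement chain mirrors standard articulographic practice: the
position channel is low-pass filtered with a zero-phase Butterworth filter
(default cutoff 30 Hz, comfortably above the band of supraglottal
articulator motion so that truncation transients are not smeared into
neighbouring landmarks),
velocity and acceleration are central differences on the filtered trace,
and the three gestural landmarks are read off zero-crossings:

* **peak velocity** — the zero-crossing of the acceleration trace at the
  dominant velocity extremum of the closing movement;
* **onset** — the nearest velocity zero-crossing before peak velocity; on
  noisy or asymptotic signals an exact crossing rarely exists, so the
  operational reading is the nearest point where |v| falls below
  max(noise floor, 1% of the movement's peak velocity), linearly
  interpolated between samples;
* **target** — the analogous point after peak velocity.

From the landmarks, the five articulatory variables follow definitionally:
acceleration phase (onset to peak velocity), deceleration phase (peak
velocity to target), displacement |x(target) - x(onset)|, peak velocity
|v| at the landmark, and the kinematic stiffness index
peak velocity / displacement (1/s).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .core import (
    DerivedTraces,
    GestureLandmarks,
    InsufficientDataError,
    KinematicRecord,
    NoGestureError,
    ParameterError,
    Trajectory,
    UndefinedStiffnessError,
)

__all__ = [
    "smooth_and_differentiate",
    "detect_landmarks",
    "compute_kinematics",
    "measure_cycles",
]


def smooth_and_differentiate(
    traj: Trajectory, cutoff: float = 30.0
) -> DerivedTraces:
    """Zero-phase low-pass smoothing followed by finite-difference derivatives.

    Parameters
    ----------
    traj
        Input trajectory; at least 9 samples.
    cutoff
        Low-pass cutoff in Hz; must lie below the Nyquist frequency.

    Returns
    -------
    DerivedTraces
        Smoothed position with velocity (mm/s) and acceleration (mm/s^2) on
        the same grid; derivatives are central differences with one-sided
        endpoints.
    """
    n = traj.times.size
    if n < 9:
        raise InsufficientDataError(
            f"need at least 9 samples to smooth and differentiate, got {n}"
        )
    nyquist = traj.sample_rate / 2.0
    if cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz"
        )
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    b, a = butter(4, cutoff, fs=traj.sample_rate)
    padlen = min(3 * (max(len(a), len(b)) - 1), n - 2)
    pos = filtfilt(b, a, traj.positions, padlen=padlen)
    dt_s = 1.0 / traj.sample_rate
    vel = np.gradient(pos, dt_s)
    acc = np.gradient(vel, dt_s)
    return DerivedTraces(
        times=traj.times, position=pos, velocity=vel, acceleration=acc,
        sample_rate=traj.sample_rate,
    )


def _interp_crossing(t0, t1, y0, y1, level=0.0):
    """Time where the line through (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return 0.5 * (t0 + t1)
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _boundary_crossing(times, v, start, stop, step, thr):
    """Scan from ``start`` towards ``stop`` for the first point where the
    directed velocity drops to ``thr`` or below; return the interpolated
    crossing time (of zero if the bracket contains a sign change, of the
    threshold otherwise), or None."""
    j = start
    while j != stop:
        nxt = j + step
        if v[nxt] <= thr:
            level = 0.0 if v[nxt] <= 0.0 < v[j] else min(thr, v[j])
            lo, hi = (j, nxt) if step > 0 else (nxt, j)
            if step < 0:
                # walking backwards: crossing lies between nxt and j
                return _interp_crossing(times[nxt], times[j], v[nxt], v[j], level)
            return _interp_crossing(times[lo], times[hi], v[lo], v[hi], level)
        j = nxt
    return None


def detect_landmarks(
    traces: DerivedTraces,
    search_window: tuple[float, float],
    direction: int | None = None,
    min_peak_velocity: float = 5.0,
    onset_frac: float = 0.01,
    noise_floor: float = 2.0,
) -> GestureLandmarks:
    """Detect onset, peak-velocity and target landmarks of one gesture.

    The window must contain exactly one closing movement (one dominant
    velocity extremum towards the constriction).  ``direction`` fixes the
    movement polarity (+1 raising, -1 lowering); if None it is taken from
    the largest velocity extremum in the window.  Landmark times are
    linearly interpolated between samples.  Detection is invariant under
    translation and sign-flip of the position trace.

    Raises
    ------
    NoGestureError
        If the window is (near) empty or the peak directed velocity stays
        below ``min_peak_velocity`` (mm/s).
    """
    lo, hi = search_window
    sel = np.nonzero((traces.times >= lo) & (traces.times <= hi))[0]
    # derivative estimates in the outermost samples carry one-sided and
    # filter-transient artefacts; keep them out of the search
    edge = 4
    sel = sel[(sel >= edge) & (sel <= traces.times.size - 1 - edge)]
    if sel.size < 3:
        raise NoGestureError(
            f"search window ({lo:.1f}, {hi:.1f}) ms contains fewer than "
            "3 samples"
        )
    i0, i1 = sel[0], sel[-1]
    v_win = traces.velocity[i0 : i1 + 1]
    if direction is None:
        direction = 1 if v_win[np.argmax(np.abs(v_win))] >= 0 else -1
    dv = direction * traces.velocity  # directed velocity, full trace

    # dominant extremum of the directed velocity; earliest wins on ties.
    # A maximum sitting exactly on the window edge is a truncated view of a
    # neighbouring movement, so an interior local maximum is preferred.
    win = dv[i0 : i1 + 1]
    interior = np.nonzero((win[1:-1] >= win[:-2]) & (win[1:-1] > win[2:]))[0] + 1
    interior = interior[win[interior] >= min_peak_velocity]
    if interior.size:
        peak_rel = int(interior[np.argmax(win[interior])])
    else:
        peak_rel = int(np.argmax(win))  # argmax returns the first maximum
    peak_idx = i0 + peak_rel
    peak_v = win[peak_rel]
    if peak_v < min_peak_velocity:
        raise NoGestureError(
            f"no movement above the noise floor: peak directed velocity "
            f"{peak_v:.2f} mm/s < {min_peak_velocity} mm/s"
        )

    # peak velocity: zero-crossing of the acceleration at the extremum,
    # located as the root of a local linear fit (+/- 3 samples) so that a
    # noisy flat velocity plateau does not scatter the crossing
    da = direction * traces.acceleration
    half = 3
    lo_i = max(peak_idx - half, i0)
    hi_i = min(peak_idx + half, i1)
    t_loc = traces.times[lo_i : hi_i + 1]
    a_loc = da[lo_i : hi_i + 1]
    pvel_ms = traces.times[peak_idx]
    if t_loc.size >= 2:
        slope, intercept = np.polyfit(t_loc - t_loc.mean(), a_loc, 1)
        if slope < 0:  # acceleration must fall through zero at the peak
            root = t_loc.mean() - intercept / slope
            step = 1000.0 / traces.sample_rate
            lo_t = traces.times[peak_idx] - (half + 1) * step
            hi_t = traces.times[peak_idx] + (half + 1) * step
            pvel_ms = float(np.clip(root, lo_t, hi_t))

    thr = max(noise_floor, onset_frac * peak_v)
    onset_ms = _boundary_crossing(traces.times, dv, peak_idx, i0, -1, thr)
    target_ms = _boundary_crossing(traces.times, dv, peak_idx, i1, +1, thr)
    # under heavy velocity noise the directed velocity may never dip below
    # the threshold; fall back to its closest approach to zero (the
    # movement turnaround) on that side of the peak
    if onset_ms is None and peak_idx > i0:
        onset_ms = traces.times[i0 + int(np.argmin(dv[i0:peak_idx]))]
    if target_ms is None and peak_idx < i1:
        target_ms = traces.times[peak_idx + 1
                                 + int(np.argmin(dv[peak_idx + 1 : i1 + 1]))]
    if onset_ms is None or target_ms is None:
        raise NoGestureError(
            "no movement boundary on one side of the velocity peak inside "
            "the search window"
        )
    # the refined crossing must stay inside the movement interval
    eps = 0.25 * 1000.0 / traces.sample_rate
    pvel_ms = float(np.clip(pvel_ms, onset_ms + eps, target_ms - eps))
    onset_pos = float(np.interp(onset_ms, traces.times, traces.position))
    target_pos = float(np.interp(target_ms, traces.times, traces.position))
    return GestureLandmarks(
        onset_ms=float(onset_ms),
        pvel_ms=float(pvel_ms),
        target_ms=float(target_ms),
        onset_pos=onset_pos,
        target_pos=target_pos,
    )


def compute_kinematics(
    traces: DerivedTraces,
    landmarks: GestureLandmarks,
    min_displacement: float = 0.1,
) -> KinematicRecord:
    """Compute variables (5)-(9) for one gesture from its landmarks.

    The acceleration and deceleration phases partition the gestural
    activation interval exactly: accel + decel = target - onset.

    Raises
    ------
    UndefinedStiffnessError
        If the displacement falls below ``min_displacement`` mm (default
        0.1 mm, the positional resolution), which leaves the stiffness
        index undefined.
    """
    accel = landmarks.pvel_ms - landmarks.onset_ms
    decel = landmarks.target_ms - landmarks.pvel_ms
    disp = abs(
        np.interp(landmarks.target_ms, traces.times, traces.position)
        - np.interp(landmarks.onset_ms, traces.times, traces.position)
    )
    pvel = abs(np.interp(landmarks.pvel_ms, traces.times, traces.velocity))
    if disp < min_displacement:
        raise UndefinedStiffnessError(
            f"displacement {disp:.3f} mm below resolution "
            f"({min_displacement} mm); stiffness undefined"
        )
    return KinematicRecord(
        accel_phase_ms=float(accel),
        decel_phase_ms=float(decel),
        displacement_mm=float(disp),
        peak_velocity_mm_s=float(pvel),
        stiffness_per_s=float(pvel / disp),
    )


def measure_cycles(
    traj: Trajectory,
    cycles,
    cutoff: float = 30.0,
    **detect_kwargs,
) -> list[tuple[GestureLandmarks, KinematicRecord]]:
    """Landmark and measure the closing gesture of each annotated cycle.

    The search window for each cycle's closing movement runs from 80% of
    the gap since the previous constriction (so it starts in the open
    phase) to 10% of a cycle after the constriction onset; this brackets
    exactly one closing movement even when cycle durations vary.  The
    closing polarity is a property of the whole train (every /pa/ closure
    raises the lower lip), so it is inferred once per trial: the sign of
    (mean position at the constriction onsets - mean position overall).
    """
    traces = smooth_and_differentiate(traj, cutoff=cutoff)
    period = float(np.median([c.duration_ms for c in cycles]))
    starts = [c.cycle_start_ms for c in cycles]
    at_constrictions = np.interp(starts, traces.times, traces.position)
    span = (traces.times >= starts[0] - period) & (
        traces.times <= cycles[-1].cycle_end_ms
    )
    overall = traces.position[span].mean() if span.any() \
        else traces.position.mean()
    direction = 1 if at_constrictions.mean() >= overall else -1
    out = []
    for k, cyc in enumerate(cycles):
        gap = starts[k] - starts[k - 1] if k > 0 else period
        window = (cyc.cycle_start_ms - 0.80 * gap,
                  cyc.cycle_start_ms + 0.10 * cyc.duration_ms)
        lm = detect_landmarks(traces, window, direction=direction,
                              **detect_kwargs)
        out.append((lm, compute_kinematics(traces, lm)))
    return out
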