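"""Synthetic cohort generation for the DDK study design.

The emulated design: 12 control speakers recorded once and 12 patients
recorded in both stimulation conditions (OFF and ON, order counterbalanced),
each producing 2 repetitions x 3 syllables (/pa, ta, ka/) of a fast
syllable-repetition train.  After discarding the first three cycles of each
train and keeping ten, 36 speaker-condition units x 6 trains x 10 cycles =
2160 tokens enter the statistical analysis.

Generating parameters per group x syllable cell are calibrated so expected
values of the simulated variables match the published group means
(:mod:`artikin.calibration`):

* cycle period      <- syllable-duration mean,
* omega             <- 1000 / acceleration-phase mean,
* closing activation<- (accel + decel)-phase mean (the gesture is truncated
  there by the opening gesture, reproducing the study's short deceleration
  phases),
* movement amplitude<- peak-velocity mean * e / omega,
* closure fraction  <- voicing-ratio mean (the vowel is fully voiced),
* Bernoulli rates   <- the printed voicing/frication proportions, realised
  with speaker-level logit intercepts whose marginal mean is bias-corrected
  back to the target proportion.

Displacement and stiffness are emergent from truncation rather than free
knobs; their group ordering matches the published tables even though their
absolute means do not (three free parameters cannot match four means).

Between-speaker and cycle-to-cycle variability are lognormal.  The printed
group coefficient of variation for a variable is split so that a fraction
``speaker_var_frac`` of the log-scale variance lies between speakers and
the rest varies independently from cycle to cycle within a train; each
speaker's standard-normal scores are drawn once and shared across that
speaker's conditions.  This is exactly the speaker-random-intercept +
independent-token-noise structure the statistical stage assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import calibration as cal
from .core import ConfigError, SyllableCycle, Trajectory, GestureLandmarks
from .gesture import AnnotationModel, DDKSpec, GestureParams, simulate_ddk_train

__all__ = [
    "CellParams",
    "CohortConfig",
    "TrialRecord",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_token_table",
    "OUTCOME_COLUMNS",
]

#: canonical outcome column names, in the study's variable order (1)-(9)
OUTCOME_COLUMNS = (
    "syllable_duration_ms",
    "voicing_ratio",
    "voicing_during_closure",
    "frication_during_closure",
    "accel_phase_ms",
    "decel_phase_ms",
    "displacement_mm",
    "peak_velocity_mm_s",
    "stiffness_per_s",
)

BINARY_OUTCOMES = ("voicing_during_closure", "frication_during_closure")

_E = math.e


@dataclass(frozen=True)
class CellParams:
    """Generating values for one group x syllable cell."""

    duration_ms: float
    duration_sd: float
    voicing_ratio: float
    ratio_sd: float
    p_voicing_closure: float
    p_frication: float
    accel_ms: float
    accel_sd: float
    decel_ms: float
    peak_velocity: float
    pvel_sd: float

    def __post_init__(self) -> None:
        for name in ("p_voicing_closure", "p_frication"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for name in ("duration_ms", "accel_ms", "decel_ms", "peak_velocity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.voicing_ratio < 1.0:
            raise ConfigError("voicing_ratio must lie in (0, 1)")


def _calibrated_cell(group: str, syll: str) -> CellParams:
    key = (group, syll)
    return CellParams(
        duration_ms=cal.SYLLABLE_DURATION_MS[key][0],
        duration_sd=cal.SYLLABLE_DURATION_MS[key][1],
        voicing_ratio=cal.VOICING_RATIO[key][0],
        ratio_sd=cal.VOICING_RATIO[key][1],
        p_voicing_closure=cal.P_VOICING_DURING_CLOSURE[key],
        p_frication=cal.P_FRICATION_DURING_CLOSURE[key],
        accel_ms=cal.ACCEL_PHASE_MS[key][0],
        accel_sd=cal.ACCEL_PHASE_MS[key][1],
        decel_ms=cal.DECEL_PHASE_MS[key][0],
        peak_velocity=cal.PEAK_VELOCITY_MM_S[key][0],
        pvel_sd=cal.PEAK_VELOCITY_MM_S[key][1],
    )


@dataclass(frozen=True)
class CohortConfig:
    """Design, calibration and noise configuration of a synthetic cohort."""

    cells: dict = field(default_factory=dict)  # (group, syllable) -> CellParams
    n_controls: int = 12
    n_patients: int = 12
    n_reps: int = 2
    n_cycles: int = 13
    syllables: tuple = cal.SYLLABLES
    sample_rate: float = 250.0
    noise_sd: float = 0.1
    phasing: float = 1.0
    #: fraction of each variable's log-scale variance between speakers
    speaker_var_frac: float = 0.7
    #: extra measurement-like lognormal noise per token (fast token path
    #: only; the trajectory path gets its measurement noise physically,
    #: from position noise passing through the landmark chain)
    token_jitter_sd: float = 0.05
    #: speaker random-intercept SD on the logit scale for binary variables
    binary_intercept_sd: float = 0.8
    #: additive shifts injected into the ON condition, keyed by outcome name;
    #: continuous outcomes in units of the cell's total log-scale SD, binary
    #: outcomes on the logit scale
    injected_effects: dict = field(default_factory=dict)
    #: additional ON-condition shifts for patients tested in ON-OFF order
    #: (same units as injected_effects); creates a DBS x order interaction
    order_effects: dict = field(default_factory=dict)

    @classmethod
    def calibrated(cls, **overrides) -> "CohortConfig":
        """Configuration calibrated to the published group tables."""
        cells = {
            (g, s): _calibrated_cell(g, s)
            for g in cal.GROUPS
            for s in cal.SYLLABLES
        }
        return cls(cells=cells, **overrides)

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """All groups share the control generating values (no group effects)."""
        cells = {
            (g, s): _calibrated_cell("control", s)
            for g in cal.GROUPS
            for s in cal.SYLLABLES
        }
        return cls(cells=cells, **overrides)

    def cell(self, group: str, syllable: str) -> CellParams:
        try:
            return self.cells[(group, syllable)]
        except KeyError:
            raise ConfigError(f"no calibration cell for {(group, syllable)}")


@dataclass
class TrialRecord:
    """One simulated DDK train with its ground truth."""

    speaker: str
    dbs: str  # control / OFF / ON
    dbs_order: str | None
    syllable: str
    rep: int
    spec: DDKSpec
    trajectory: Trajectory
    landmarks: list[GestureLandmarks]
    cycles: list[SyllableCycle]

    @property
    def trial_id(self) -> str:
        return f"{self.speaker}_{self.dbs}_{self.syllable}_{self.rep}"


@dataclass
class SyntheticCohort:
    """A full synthetic cohort: subjects, trials, and their provenance."""

    subjects: pd.DataFrame
    trials: list[TrialRecord]
    config: CohortConfig
    seed: int

    def annotation_table(self) -> pd.DataFrame:
        """All annotation tiers as one long table (one row per cycle)."""
        rows = []
        for tr in self.trials:
            for cyc in tr.cycles:
                voiced_clo = sum(
                    max(0.0, min(e, cyc.closure_end_ms) - max(s, cyc.closure_start_ms))
                    for s, e in cyc.voiced_spans
                )
                rows.append(
                    {
                        "speaker": tr.speaker,
                        "condition": tr.dbs,
                        "order": tr.dbs_order or "",
                        "syllable": tr.syllable,
                        "rep": tr.rep,
                        "cycle_index": cyc.cycle_index,
                        "cycle_start_ms": cyc.cycle_start_ms,
                        "cycle_end_ms": cyc.cycle_end_ms,
                        "closure_start_ms": cyc.closure_start_ms,
                        "closure_end_ms": cyc.closure_end_ms,
                        "vowel_start_ms": cyc.vowel_start_ms,
                        "vowel_end_ms": cyc.vowel_end_ms,
                        "voiced_ms_in_closure": voiced_clo,
                        "frication_flag": cyc.frication_flag,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variability helpers


def _log_sd(cv: float) -> float:
    """Lognormal log-scale SD matching a coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def _lognormal(mean: float, sd_log: float, z: float) -> float:
    """Lognormal draw with exact mean ``mean`` given standard score ``z``."""
    return mean * math.exp(z * sd_log - 0.5 * sd_log * sd_log)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(31)


def _logit_offset(p: float, sd: float) -> float:
    """Logit intercept whose logit-normal marginal mean equals ``p``.

    With speaker intercepts u ~ N(0, sd^2) the marginal
    E[expit(mu + u)] generally differs from expit(mu); this inverts the
    Gauss-Hermite approximation of that expectation so the generated
    group proportion is unbiased.
    """
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    if sd == 0.0:
        return float(logit(p))

    def marginal(mu: float) -> float:
        vals = expit(mu + math.sqrt(2.0) * sd * _GH_NODES)
        return float(np.sum(_GH_WEIGHTS * vals) / math.sqrt(math.pi)) - p

    return float(brentq(marginal, -20.0, 20.0))


@dataclass(frozen=True)
class _SpeakerScores:
    """Standard-normal speaker scores, drawn once and shared across conditions."""

    duration: float
    frequency: float
    amplitude: float
    ratio: float
    voicing: float
    frication: float


def _draw_speaker_scores(rng: np.random.Generator) -> _SpeakerScores:
    z = rng.standard_normal(6)
    return _SpeakerScores(*z)


@dataclass(frozen=True)
class _UnitParams:
    """Resolved speaker-level generating values for one condition x syllable.

    Cycle-to-cycle variability sits on top of these as mean-one lognormal
    multipliers with the ``sd_cyc_*`` log-scale SDs.
    """

    period: float
    omega: float          # compensated so E[1/omega_cycle] = accel target
    accel_ms: float
    close_ms: float       # closing activation (accel + decel target)
    amplitude: float
    pvel: float
    closure_frac: float
    p_vdc: float
    p_fric: float
    sd_cyc_dur: float
    sd_cyc_accel: float
    sd_cyc_amp: float


def _total_shift(config: CohortConfig, dbs: str, dbs_order: str | None,
                 outcome: str) -> float:
    """Injected effect (SD units / logit shift) for one token's condition."""
    d = 0.0
    if dbs == "ON":
        d += config.injected_effects.get(outcome, 0.0)
        if dbs_order == "ON-OFF":
            d += config.order_effects.get(outcome, 0.0)
    return d


def _resolve_unit(
    config: CohortConfig,
    cell: CellParams,
    scores: _SpeakerScores,
    dbs: str,
    dbs_order: str | None,
    ann_span_means: tuple[float, float],
) -> _UnitParams:
    f_sp = math.sqrt(config.speaker_var_frac)
    f_cyc = math.sqrt(1.0 - config.speaker_var_frac)

    def draw(mean: float, cv: float, z_speaker: float, outcome: str) -> float:
        sd_sp = f_sp * _log_sd(cv)
        val = _lognormal(mean, sd_sp, z_speaker)
        shift = _total_shift(config, dbs, dbs_order, outcome)
        if shift:
            val *= math.exp(shift * _log_sd(cv))
        return val

    period = draw(cell.duration_ms, cell.duration_sd / cell.duration_ms,
                  scores.duration, "syllable_duration_ms")
    accel = draw(cell.accel_ms, cell.accel_sd / cell.accel_ms,
                 scores.frequency, "accel_phase_ms")
    accel = min(max(accel, 8.0), 0.45 * period)  # keep omega and truncation sane
    pvel = draw(cell.peak_velocity, cell.pvel_sd / cell.peak_velocity,
                scores.amplitude, "peak_velocity_mm_s")
    pvel = max(pvel, 20.0)  # every study token was measurable by hand
    sd_cyc_accel = f_cyc * _log_sd(cell.accel_sd / cell.accel_ms)
    # the cycle-level frequency multiplier is mean-one on omega; compensate
    # the base so the mean *acceleration phase* (1/omega) stays on target
    omega = (1000.0 / accel) * math.exp(sd_cyc_accel**2)
    close_frac = (cell.accel_ms + cell.decel_ms) / cell.duration_ms
    close_ms = close_frac * period

    # closure fraction from the speaker-level voicing ratio
    sd_ratio = _log_sd(cell.ratio_sd / cell.voicing_ratio) * f_sp
    ratio_sp = _lognormal(cell.voicing_ratio, sd_ratio, scores.ratio)
    ratio_sp = min(max(ratio_sp, 0.1), 0.9)
    mean_span = (cell.p_voicing_closure * ann_span_means[0]
                 + (1.0 - cell.p_voicing_closure) * ann_span_means[1])
    closure_frac = 1.0 - ratio_sp + mean_span / period
    closure_frac = min(max(closure_frac, 0.15), 0.85)

    sd_b = config.binary_intercept_sd
    p_vdc = expit(_logit_offset(cell.p_voicing_closure, sd_b)
                  + sd_b * scores.voicing
                  + _total_shift(config, dbs, dbs_order, "voicing_during_closure"))
    p_fric = expit(_logit_offset(cell.p_frication, sd_b)
                   + sd_b * scores.frication
                   + _total_shift(config, dbs, dbs_order, "frication_during_closure"))
    # cycle-level peak-velocity spread: part comes through the frequency
    # multiplier (pvel = amp * omega / e), the rest through the amplitude
    sd_cyc_pvel = f_cyc * _log_sd(cell.pvel_sd / cell.peak_velocity)
    sd_cyc_amp = math.sqrt(max(sd_cyc_pvel**2 - sd_cyc_accel**2, 1e-4))
    # a stop closure requires a minimum excursion to occlude the tract
    amplitude = max(pvel * _E / omega, 2.0)
    return _UnitParams(
        period=period, omega=omega, accel_ms=accel, close_ms=close_ms,
        amplitude=amplitude, pvel=amplitude * omega / _E,
        closure_frac=closure_frac,
        p_vdc=float(p_vdc), p_fric=float(p_fric),
        sd_cyc_dur=f_cyc * _log_sd(cell.duration_sd / cell.duration_ms),
        sd_cyc_accel=sd_cyc_accel,
        sd_cyc_amp=sd_cyc_amp,
    )


def _speaker_conditions(config: CohortConfig, rng: np.random.Generator):
    """Subject table rows and the per-speaker standard scores, in fixed order."""
    subjects = []
    scores = {}
    for i in range(config.n_controls):
        sid = f"C{i + 1:02d}"
        subjects.append({"speaker": sid, "group": "control", "dbs_order": ""})
        scores[sid] = _draw_speaker_scores(rng)
    orders = ["OFF-ON"] * (config.n_patients // 2)
    orders += ["ON-OFF"] * (config.n_patients - len(orders))
    orders = list(rng.permutation(orders))
    for i in range(config.n_patients):
        sid = f"P{i + 1:02d}"
        subjects.append({"speaker": sid, "group": "patient",
                         "dbs_order": orders[i]})
        scores[sid] = _draw_speaker_scores(rng)
    return pd.DataFrame(subjects), scores


def _iter_units(subjects: pd.DataFrame):
    """Yield (speaker, dbs, dbs_order) speaker-condition units in fixed order."""
    for row in subjects.itertuples(index=False):
        if row.group == "control":
            yield row.speaker, "control", None
        else:
            yield row.speaker, "OFF", row.dbs_order
            yield row.speaker, "ON", row.dbs_order


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Simulate the full cohort: trajectories, ground truth, annotations.

    All randomness flows from one seeded generator; speaker intercepts are
    drawn first, in a fixed order, before any token-level noise, so the
    same seed yields an identical cohort.
    """
    if not config.cells:
        raise ConfigError(
            "config has no calibration cells; use CohortConfig.calibrated() "
            "or CohortConfig.null()"
        )
    rng = np.random.default_rng(seed)
    subjects, scores = _speaker_conditions(config, rng)
    ann_default = AnnotationModel()
    span_means = (
        0.5 * sum(ann_default.voiced_span_ms),
        0.5 * sum(ann_default.coart_span_ms),
    )

    trials = []
    for speaker, dbs, order in _iter_units(subjects):
        for syll in config.syllables:
            cell = config.cell(dbs, syll)
            tp = _resolve_unit(config, cell, scores[speaker], dbs, order,
                               span_means)
            for rep in range(1, config.n_reps + 1):
                annotation = AnnotationModel(
                    closure_frac=tp.closure_frac,
                    p_voice_closure=tp.p_vdc,
                    p_frication=tp.p_fric,
                )
                spec = DDKSpec(
                    syllable=syll,
                    n_cycles=config.n_cycles,
                    cycle_period=tp.period,
                    closing_params=GestureParams(
                        target_pos=tp.amplitude, rest_pos=0.0,
                        natural_freq=tp.omega,
                        activation_onset=0.0, activation_offset=tp.close_ms,
                    ),
                    opening_params=GestureParams(
                        target_pos=0.0, rest_pos=tp.amplitude,
                        natural_freq=tp.omega,
                        activation_onset=0.0,
                        activation_offset=tp.period - tp.close_ms,
                    ),
                    phasing=config.phasing,
                    noise_sd=config.noise_sd,
                    sample_rate=config.sample_rate,
                    seed=int(rng.integers(2**31)),
                    annotation=annotation,
                    cycle_jitter_sd=tp.sd_cyc_dur,
                    freq_jitter_sd=tp.sd_cyc_accel,
                    amplitude_jitter_sd=tp.sd_cyc_amp,
                    min_cycle_peak_velocity=20.0,
                    min_opening_recovery=0.85,
                    min_cycle_amplitude=1.5,
                )
                traj, landmarks, cycles = simulate_ddk_train(spec)
                trials.append(
                    TrialRecord(
                        speaker=speaker, dbs=dbs, dbs_order=order,
                        syllable=syll, rep=rep, spec=spec,
                        trajectory=traj, landmarks=landmarks, cycles=cycles,
                    )
                )
    return SyntheticCohort(subjects=subjects, trials=trials, config=config,
                           seed=seed)


def simulate_token_table(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw the analysis token table directly from the generative model.

    Bypasses trajectory synthesis and landmark measurement: every token's
    nine variables are computed from the same generating quantities the
    trajectory path realises (closed-form truncated-gesture kinematics plus
    lognormal cycle-level jitter).  Used for simulation studies of the
    statistical stage, where thousands of cohorts are needed.

    Returns one row per token with identifiers
    (speaker, dbs, dbs_order, syllable, rep, cycle_position 1-10) and the
    nine outcome columns.
    """
    if not config.cells:
        raise ConfigError("config has no calibration cells")
    rng = np.random.default_rng(seed)
    subjects, scores = _speaker_conditions(config, rng)
    ann_default = AnnotationModel()
    span_means = (
        0.5 * sum(ann_default.voiced_span_ms),
        0.5 * sum(ann_default.coart_span_ms),
    )
    s_tok = config.token_jitter_sd

    rows = []
    for speaker, dbs, order in _iter_units(subjects):
        for syll in config.syllables:
            cell = config.cell(dbs, syll)
            tp = _resolve_unit(config, cell, scores[speaker], dbs, order,
                               span_means)
            sd_dur = math.hypot(tp.sd_cyc_dur, s_tok)
            sd_acc = math.hypot(tp.sd_cyc_accel, s_tok)
            sd_amp = math.hypot(tp.sd_cyc_amp, s_tok)
            for rep in range(1, config.n_reps + 1):
                for pos in range(1, 11):
                    z = rng.standard_normal(3)
                    dur = _lognormal(tp.period, sd_dur, z[0])
                    omega = tp.omega * _lognormal(1.0, sd_acc, z[1])
                    amp = tp.amplitude * _lognormal(1.0, sd_amp, z[2])
                    accel = 1000.0 / omega
                    pvel = amp * omega / _E
                    close_ms = tp.close_ms * dur / tp.period
                    decel = max(close_ms - accel, 2.0)
                    u = omega * close_ms / 1000.0
                    disp = amp * (1.0 - (1.0 + u) * math.exp(-u))
                    voiced_clo = (
                        rng.uniform(*ann_default.voiced_span_ms)
                        if rng.random() < tp.p_vdc
                        else rng.uniform(*ann_default.coart_span_ms)
                    )
                    d_clo = tp.closure_frac * dur
                    voiced_clo = min(voiced_clo, d_clo)
                    ratio = min(((dur - d_clo) + voiced_clo) / dur, 1.0)
                    rows.append(
                        {
                            "speaker": speaker,
                            "dbs": dbs,
                            "dbs_order": order or "",
                            "syllable": syll,
                            "rep": rep,
                            "cycle_position": pos,
                            "syllable_duration_ms": dur,
                            "voicing_ratio": ratio,
                            "voicing_during_closure": int(voiced_clo > 20.0),
                            "frication_during_closure": int(rng.random() < tp.p_fric),
                            "accel_phase_ms": accel,
                            "decel_phase_ms": decel,
                            "displacement_mm": disp,
                            "peak_velocity_mm_s": pvel,
                            "stiffness_per_s": pvel / disp,
                        }
                    )
    return pd.DataFrame(rows)
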