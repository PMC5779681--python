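"""Shared fixtures: canonical gesture/train specifications and cohort runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from artikin import calibration as cal
from artikin.core import TruncationWarning
from artikin.gesture import DDKSpec, GestureParams


def make_cell_spec(group: str, syllable: str, noise_sd: float = 0.0,
                   n_cycles: int = 13, seed: int = 1, **kwargs) -> DDKSpec:
    """A DDK train spec whose parameters match one calibrated group cell."""
    period = cal.SYLLABLE_DURATION_MS[(group, syllable)][0]
    accel = cal.ACCEL_PHASE_MS[(group, syllable)][0]
    decel = cal.DECEL_PHASE_MS[(group, syllable)][0]
    pvel = cal.PEAK_VELOCITY_MM_S[(group, syllable)][0]
    omega = 1000.0 / accel
    close_ms = accel + decel
    amp = pvel * np.e / omega
    return DDKSpec(
        syllable=syllable,
        n_cycles=n_cycles,
        cycle_period=period,
        closing_params=GestureParams(amp, 0.0, omega, 0.0, close_ms),
        opening_params=GestureParams(0.0, amp, omega, 0.0, period - close_ms),
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(autouse=True)
def _quiet_truncation():
    # the calibrated cells are deliberately in the truncation regime
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TruncationWarning)
        yield


@pytest.fixture(scope="session")
def pipeline_result():
    """One full calibrated pipeline run shared across tests."""
    from artikin.io import RunConfig
    from artikin.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TruncationWarning)
        return run_pipeline(RunConfig(seed=1))


def match_landmarks(truth, cycles, measured):
    """Pair measured landmarks with ground truth by constriction time."""
    pairs = []
    for cyc, (lm, kin) in zip(cycles, measured):
        gt = min(truth, key=lambda g: abs(g.target_ms - cyc.cycle_start_ms))
        pairs.append((gt, lm, kin))
    return pairs
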