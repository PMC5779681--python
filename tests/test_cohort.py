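"""Synthetic cohort generation: design arithmetic, calibration, sharing."""

import numpy as np
import pandas as pd
import pytest

from artikin.cohort import (
    CellParams,
    CohortConfig,
    _logit_offset,
    generate_cohort,
    simulate_token_table,
)
from artikin.core import ConfigError
from scipy.special import expit


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ConfigError):
            CellParams(
                duration_ms=150.0, duration_sd=15.0, voicing_ratio=0.5,
                ratio_sd=0.1, p_voicing_closure=1.4, p_frication=0.1,
                accel_ms=32.0, accel_sd=5.0, decel_ms=44.0,
                peak_velocity=95.0, pvel_sd=35.0,
            )

    def test_empty_config_rejected(self):
        with pytest.raises(ConfigError, match="calibration cells"):
            generate_cohort(CohortConfig(), 1)

    def test_null_config_equalises_groups(self):
        cfg = CohortConfig.null()
        for syll in ("pa", "ta", "ka"):
            assert cfg.cell("OFF", syll) == cfg.cell("control", syll)
            assert cfg.cell("ON", syll) == cfg.cell("control", syll)


class TestLogitOffset:
    @pytest.mark.parametrize("p", [0.05, 0.26, 0.44, 0.65, 0.86])
    def test_marginal_mean_is_unbiased(self, p):
        """E[expit(mu + sd*Z)] over the intercept distribution equals p."""
        mu = _logit_offset(p, 0.8)
        z = np.random.default_rng(0).standard_normal(200_000)
        assert expit(mu + 0.8 * z).mean() == pytest.approx(p, abs=0.003)


class TestTokenTable:
    def test_design_arithmetic(self):
        """12 + 12x2 speaker-conditions x 3 POA x 2 reps x 10 cycles = 2160."""
        table = simulate_token_table(CohortConfig.calibrated(), 1)
        assert len(table) == 2160
        units = table.groupby(["speaker", "dbs"]).ngroups
        assert units == 36
        assert table.groupby(["speaker", "dbs", "syllable", "rep"]).size().eq(
            10).all()
        patients = table[table.speaker.str.startswith("P")]
        assert set(patients["dbs"]) == {"OFF", "ON"}
        assert set(patients["dbs_order"]) == {"OFF-ON", "ON-OFF"}

    def test_deterministic_under_seed(self):
        a = simulate_token_table(CohortConfig.calibrated(), 9)
        b = simulate_token_table(CohortConfig.calibrated(), 9)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_token_table(CohortConfig.calibrated(), 10)
        assert not a["syllable_duration_ms"].equals(c["syllable_duration_ms"])

    def test_speaker_intercepts_shared_across_conditions(self):
        """A patient slow in OFF is slow in ON: speaker means correlate."""
        table = simulate_token_table(CohortConfig.null(), 4)
        per = table[table.dbs.isin(("OFF", "ON"))].groupby(
            ["speaker", "dbs"])["syllable_duration_ms"].mean().unstack()
        r = np.corrcoef(np.log(per["OFF"]), np.log(per["ON"]))[0, 1]
        assert r > 0.8

    def test_calibrated_group_means(self):
        """Control /pa/ syllable duration lands within 2 cluster SEM of 151."""
        table = simulate_token_table(CohortConfig.calibrated(), 2)
        cp = table[(table.dbs == "control") & (table.syllable == "pa")]
        speaker_means = cp.groupby("speaker")["syllable_duration_ms"].mean()
        sem = speaker_means.std(ddof=1) / np.sqrt(len(speaker_means))
        assert abs(speaker_means.mean() - 151.0) <= 2 * sem

    def test_binary_rates_track_calibration(self):
        """Pooled over seeds, group proportions approach the table values."""
        tables = [simulate_token_table(CohortConfig.calibrated(), s)
                  for s in range(4)]
        table = pd.concat(tables)
        on_ta = table[(table.dbs == "ON") & (table.syllable == "ta")]
        assert on_ta["voicing_during_closure"].mean() == pytest.approx(
            0.84, abs=0.08)
        ctrl_pa = table[(table.dbs == "control") & (table.syllable == "pa")]
        assert ctrl_pa["frication_during_closure"].mean() == pytest.approx(
            0.05, abs=0.05)

    def test_injected_effect_shifts_on_only(self):
        cfg = CohortConfig.null(injected_effects={"syllable_duration_ms": 1.0})
        table = simulate_token_table(cfg, 5)
        base = simulate_token_table(CohortConfig.null(), 5)
        on_ratio = (table[table.dbs == "ON"]["syllable_duration_ms"].mean()
                    / base[base.dbs == "ON"]["syllable_duration_ms"].mean())
        off_ratio = (table[table.dbs == "OFF"]["syllable_duration_ms"].mean()
                     / base[base.dbs == "OFF"]["syllable_duration_ms"].mean())
        assert on_ratio > 1.05
        assert off_ratio == pytest.approx(1.0, abs=1e-12)


class TestFullCohort:
    def test_cohort_structure_and_determinism(self):
        cfg = CohortConfig.calibrated(n_controls=2, n_patients=2)
        cohort = generate_cohort(cfg, 3)
        # 2 controls + 2 patients x 2 conditions = 6 units x 3 syll x 2 reps
        assert len(cohort.trials) == 36
        assert len(cohort.subjects) == 4
        for trial in cohort.trials:
            assert len(trial.cycles) == cfg.n_cycles
            assert len(trial.landmarks) == cfg.n_cycles
        again = generate_cohort(cfg, 3)
        for a, b in zip(cohort.trials, again.trials):
            assert np.array_equal(a.trajectory.positions,
                                  b.trajectory.positions)

    def test_annotation_table_schema(self):
        cfg = CohortConfig.calibrated(n_controls=1, n_patients=1)
        ann = generate_cohort(cfg, 8).annotation_table()
        assert len(ann) == 3 * 13 * 2 * 3  # units x cycles x syll... rows
        assert {"speaker", "condition", "cycle_start_ms",
                "voiced_ms_in_closure", "frication_flag"} <= set(ann.columns)
        assert (ann["cycle_end_ms"] > ann["cycle_start_ms"]).all()

    def test_trajectory_and_fast_paths_agree_on_group_means(self):
        """Measured durations from trajectories track the generative draw."""
        from artikin.io import RunConfig
        from artikin.pipeline import build_token_table

        run = RunConfig(seed=6, n_controls=4, n_patients=4)
        cfg = CohortConfig.calibrated(n_controls=4, n_patients=4)
        cohort = generate_cohort(cfg, 6)
        measured = build_token_table(cohort, run)
        fast = simulate_token_table(cfg, 6)
        for dbs in ("control", "OFF", "ON"):
            m = measured[measured.dbs == dbs]["syllable_duration_ms"].mean()
            f = fast[fast.dbs == dbs]["syllable_duration_ms"].mean()
            assert m == pytest.approx(f, rel=0.15)
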