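"""Transforms, Šidák correction, model selection, and cohort summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import artikin
from artikin.cohort import CohortConfig, simulate_token_table
from artikin.core import ConfigError, DataError
from artikin.stats import (
    _build_design,
    fit_and_compare,
    order_effect_analysis,
    sidak_alpha,
    summarize_cohort,
    transform_continuous,
)


class TestTransformContinuous:
    def test_closed_form_example(self):
        """{e, e^2, e^3} -> log {1,2,3} -> scaled {-1, 0, 1}."""
        out = transform_continuous([np.e, np.e**2, np.e**3])
        assert out == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)

    def test_all_equal_maps_to_zeros(self):
        assert np.all(transform_continuous([5.0, 5.0, 5.0, 5.0]) == 0.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            transform_continuous([1.0, 0.0, 2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e6), min_size=3, max_size=40,
                    unique=True))
    def test_monotone_rank_preserving(self, values):
        out = transform_continuous(sorted(values))
        assert np.all(np.diff(out) >= 0.0)


class TestSidakAlpha:
    def test_published_family_levels(self):
        assert sidak_alpha(0.05, 4) == 0.0127  # four acoustic variables
        assert sidak_alpha(0.05, 5) == 0.0102  # five articulatory variables
        assert sidak_alpha(0.05, 1) == 0.05

    def test_inverts_to_family_level(self):
        for m in (1, 2, 4, 5, 20):
            a = sidak_alpha(0.05, m, digits=None)
            assert 1.0 - (1.0 - a) ** m == pytest.approx(0.05, abs=1e-12)

    def test_strictly_decreasing_in_m(self):
        levels = [sidak_alpha(0.05, m, digits=None) for m in range(1, 30)]
        assert np.all(np.diff(levels) < 0)

    def test_usage_errors(self):
        with pytest.raises(ConfigError):
            sidak_alpha(0.05, 0)
        with pytest.raises(ConfigError):
            sidak_alpha(1.5, 4)


class TestDesignCoding:
    def test_deviation_coded_columns_sum_to_zero(self):
        """On a balanced table every factor column sums to zero."""
        table = simulate_token_table(CohortConfig.null(), 3)
        sub = table[table["dbs"].isin(("OFF", "ON"))].reset_index(drop=True)
        X, names = _build_design(sub, ("OFF", "ON"))
        for j, name in enumerate(names):
            if name == "Intercept":
                continue
            assert abs(X[:, j].sum()) < 1e-9, name
        # interaction columns are elementwise products of their factors
        i_dbs = names.index("DBS[OFF]")
        i_poa = names.index("POA[pa]")
        i_int = names.index("DBS[OFF]:POA[pa]")
        assert np.array_equal(X[:, i_int], X[:, i_dbs] * X[:, i_poa])


@pytest.fixture(scope="module")
def effect_table():
    """Token table with a strong pure main effect of DBS on duration."""
    config = CohortConfig.null(
        injected_effects={"syllable_duration_ms": 1.0})
    return simulate_token_table(config, 101)


class TestFitAndCompare:
    def test_interaction_df_and_decision_flow(self, effect_table):
        res = fit_and_compare(effect_table, "syllable_duration_ms",
                              comparison=("OFF", "ON"), m=4)
        assert res[0].comparison == "interaction DBS x POA"
        assert res[0].df == 2
        assert res[0].alpha_corrected == 0.0127
        if not res[0].significant:  # pure main effect: usually n.s.
            assert res[1].comparison == "main DBS"
            assert res[1].df == 1
            assert res[1].significant  # 1 SD shift is unmissable
            assert res[1].p_value < 1e-6
        for r in res:
            assert r.converged
            assert (r.p_value < r.alpha_corrected) == r.significant

    def test_binomial_outcome_uses_mixed_logit(self, effect_table):
        res = fit_and_compare(effect_table, "voicing_during_closure",
                              comparison=("OFF", "ON"), m=4)
        assert all(r.converged for r in res)
        assert {"DBS[OFF]", "POA[pa]"} <= set(res[0].coefficients.index)

    def test_missing_level_rejected(self, effect_table):
        only_off = effect_table[effect_table["dbs"] == "OFF"]
        with pytest.raises(DataError):
            fit_and_compare(only_off, "syllable_duration_ms",
                            comparison=("OFF", "ON"))


class TestOrderEffects:
    def test_single_order_group_skips_with_warning(self, effect_table):
        one_order = effect_table[effect_table["dbs_order"] != "ON-OFF"]
        with pytest.warns(UserWarning, match="order"):
            out = order_effect_analysis(one_order, "syllable_duration_ms",
                                        comparison=("OFF", "ON"))
        assert out == []

    def test_control_vs_off_split(self, effect_table):
        res = order_effect_analysis(effect_table, "syllable_duration_ms",
                                    comparison=("control", "OFF"), m=4)
        assert len(res) == 1
        assert res[0].df == 1
        assert res[0].note == "exploratory"

    def test_off_vs_on_interaction_then_main(self):
        config = CohortConfig.null(
            order_effects={"syllable_duration_ms": 1.0})
        table = simulate_token_table(config, 7)
        res = order_effect_analysis(table, "syllable_duration_ms",
                                    comparison=("OFF", "ON"), m=4)
        assert res[0].comparison == "interaction DBS x order"
        assert res[0].significant  # injected interaction is large


class TestSummarizeCohort:
    def test_published_subject_table(self):
        """Means/SDs of the 12-patient subject table match the print."""
        table = artikin.load_cohort_characteristics()
        out = summarize_cohort(table.drop(columns=["subject"]))
        assert out.loc["patient_age", "mean"] == 61.58
        assert out.loc["patient_age", "std"] == 11.93
        assert out.loc["disease_duration_y", "mean"] == 16.75
        assert out.loc["disease_duration_y", "std"] == 12.40
        assert out.loc["dbs_months", "mean"] == 49.08
        assert out.loc["control_age", "mean"] == 60.92
        assert out.loc["control_age", "std"] == 12.31

    def test_single_observation_has_missing_sd(self):
        out = summarize_cohort(pd.DataFrame({"x": [3.0]}))
        assert out.loc["x", "mean"] == 3.0
        assert pd.isna(out.loc["x", "std"])

    def test_grouped_summary(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"],
                           "x": [1.0, 3.0, 10.0, 14.0]})
        out = summarize_cohort(df, group_col="g")
        assert out.loc["a", ("x", "mean")] == 2.0
        assert out.loc["b", ("x", "std")] == pytest.approx(2.83, abs=0.01)
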