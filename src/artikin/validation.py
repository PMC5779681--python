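"""Simulation studies of the statistical stage.

These harnesses draw replicate synthetic cohorts through the fast
token-level path (:func:`artikin.cohort.simulate_token_table`) and push
them through the exact model-selection procedure the pipeline uses, to
check its operating characteristics:

* **null calibration** — with zero group effects, how often does each
  variable family produce at least one rejection at its Šidák-corrected
  alpha (the family-wise error rate)?
* **power** — how often is an injected DBS main effect of a given size
  (in total log-scale SD units) detected?
* **order power** — detection rate for an injected DBS x order
  interaction in the exploratory order analysis.

The null simulation uses the within-subject OFF-vs-ON contrast, the
study's central comparison and the one for which the chi-square reference
distribution of the LRT is well calibrated at this design size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_token_table
from .stats import (
    ACOUSTIC_OUTCOMES,
    ARTICULATORY_OUTCOMES,
    fit_and_compare,
    order_effect_analysis,
)

__all__ = [
    "EXPECTED_DIRECTIONS",
    "rejects_dbs",
    "null_simulation",
    "familywise_error",
    "power_simulation",
    "order_power_simulation",
    "direction_concordance",
]

#: Significant group effects reported by the study and their direction,
#: as (outcome, (lower group, higher group)).  Used by
#: :func:`direction_concordance`.
EXPECTED_DIRECTIONS = {
    ("control", "OFF"): [
        ("syllable_duration_ms", ("control", "OFF")),
        ("frication_during_closure", ("control", "OFF")),
        ("accel_phase_ms", ("control", "OFF")),
        ("decel_phase_ms", ("control", "OFF")),
        ("stiffness_per_s", ("OFF", "control")),
    ],
    ("OFF", "ON"): [
        ("syllable_duration_ms", ("OFF", "ON")),
        ("voicing_ratio", ("OFF", "ON")),
        ("voicing_during_closure", ("OFF", "ON")),
        ("frication_during_closure", ("OFF", "ON")),
        ("accel_phase_ms", ("OFF", "ON")),
        ("decel_phase_ms", ("OFF", "ON")),
        ("displacement_mm", ("ON", "OFF")),
        ("peak_velocity_mm_s", ("ON", "OFF")),
        ("stiffness_per_s", ("ON", "OFF")),
    ],
}

_FAMILIES = {"acoustic": ACOUSTIC_OUTCOMES, "articulatory": ARTICULATORY_OUTCOMES}
_FAMILY_M = {"acoustic": 4, "articulatory": 5}


def rejects_dbs(results) -> bool:
    """True if the selection procedure rejected for DBS (interaction or main)."""
    return any(r.significant for r in results)


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=n_reps)


def null_simulation(
    n_reps: int = 500,
    seed: int = 0,
    comparison: tuple[str, str] = ("OFF", "ON"),
    outcomes=None,
    base_config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Replicate the analysis on cohorts generated without group effects.

    Returns one row per replicate x outcome with the interaction and (when
    reached) main-effect p-values and the family-level rejection decision.
    """
    config = base_config if base_config is not None else CohortConfig.null()
    if outcomes is None:
        outcomes = ACOUSTIC_OUTCOMES + ARTICULATORY_OUTCOMES
    fam_of = {o: f for f, outs in _FAMILIES.items() for o in outs}
    rows = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_reps)):
        table = simulate_token_table(config, int(rep_seed))
        for outcome in outcomes:
            m = _FAMILY_M[fam_of[outcome]]
            res = fit_and_compare(table, outcome, comparison=comparison, m=m)
            rows.append(
                {
                    "rep": rep,
                    "outcome": outcome,
                    "family": fam_of[outcome],
                    "p_interaction": res[0].p_value,
                    "p_main": res[1].p_value if len(res) > 1 else np.nan,
                    "rejected": rejects_dbs(res),
                    "converged": all(r.converged for r in res),
                }
            )
    return pd.DataFrame(rows)


def familywise_error(null_results: pd.DataFrame) -> dict[str, float]:
    """Per-family fraction of replicates with at least one rejection."""
    fam = null_results.groupby(["family", "rep"])["rejected"].any()
    return fam.groupby(level="family").mean().to_dict()


def power_simulation(
    effect_sd: float = 0.5,
    outcome: str = "syllable_duration_ms",
    n_reps: int = 200,
    seed: int = 0,
    comparison: tuple[str, str] = ("OFF", "ON"),
) -> pd.DataFrame:
    """Detection of an injected ON-condition main effect (no interaction).

    The effect is a shift of ``effect_sd`` total log-scale SDs (logit shift
    for binary outcomes) applied uniformly across places of articulation.
    """
    config = CohortConfig.null(injected_effects={outcome: effect_sd})
    fam_of = {o: f for f, outs in _FAMILIES.items() for o in outs}
    m = _FAMILY_M[fam_of[outcome]]
    rows = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_reps)):
        table = simulate_token_table(config, int(rep_seed))
        res = fit_and_compare(table, outcome, comparison=comparison, m=m)
        rows.append(
            {
                "rep": rep,
                "detected": rejects_dbs(res),
                "p_interaction": res[0].p_value,
                "interaction_significant": res[0].significant,
                "p_main": res[1].p_value if len(res) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def order_power_simulation(
    effect_sd: float = 0.75,
    outcome: str = "syllable_duration_ms",
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection of an injected DBS x order interaction (OFF-vs-ON)."""
    config = CohortConfig.null(order_effects={outcome: effect_sd})
    fam_of = {o: f for f, outs in _FAMILIES.items() for o in outs}
    m = _FAMILY_M[fam_of[outcome]]
    rows = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_reps)):
        table = simulate_token_table(config, int(rep_seed))
        res = order_effect_analysis(table, outcome, comparison=("OFF", "ON"),
                                    m=m)
        inter = next(r for r in res if "interaction" in r.comparison)
        rows.append(
            {
                "rep": rep,
                "detected": inter.significant,
                "p_interaction": inter.p_value,
            }
        )
    return pd.DataFrame(rows)


def direction_concordance(tokens: pd.DataFrame) -> pd.DataFrame:
    """Check the sign of each study-reported significant effect.

    For each expected effect, compares the overall group means in the
    measured token table (proportions for the binary variables) and
    reports whether the ordering matches.
    """
    rows = []
    for comparison, effects in EXPECTED_DIRECTIONS.items():
        for outcome, (low, high) in effects:
            means = tokens.groupby("dbs")[outcome].mean()
            diff = means[high] - means[low]
            rows.append(
                {
                    "contrast": f"{comparison[0]} vs {comparison[1]}",
                    "outcome": outcome,
                    "expected_higher": high,
                    "mean_low": means[low],
                    "mean_high": means[high],
                    "concordant": bool(diff > 0),
                }
            )
    return pd.DataFrame(rows)
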