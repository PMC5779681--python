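"""The inference stage: mixed models, LRT model selection, multiplicity.

For each outcome the full model is

    outcome ~ DBS * POA + cycle_position_centred + (1 | speaker)

with deviation-coded (sum-to-zero) contrasts, fitted by maximum
likelihood — Gaussian for the continuous variables (log-transformed, then
z-scaled over the analysis set; the stiffness index is z-scaled without
log), binomial (mixed logit) for the two binary variables.  Model
selection is by likelihood-ratio test: first the DBS x POA interaction
against the additive model (df = 2 for 2 x 3 factors); if the interaction
is not significant at the corrected alpha, the DBS main effect against the
model without DBS (df = 1).

Exactly one DBS contrast enters an analysis: control vs OFF (between
speakers) or OFF vs ON (within speakers).  Multiplicity is controlled per
variable family (4 acoustic, 5 articulatory) with the Dunn-Šidák
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BINARY_OUTCOMES, OUTCOME_COLUMNS
from .core import ConfigError, DataError
from .mixedmodels import (
    MixedFitResult,
    fit_lmm,
    fit_logit_glmm,
    likelihood_ratio_test,
)

__all__ = [
    "ModelComparison",
    "ACOUSTIC_OUTCOMES",
    "ARTICULATORY_OUTCOMES",
    "transform_continuous",
    "sidak_alpha",
    "fit_and_compare",
    "order_effect_analysis",
    "summarize_cohort",
]

ACOUSTIC_OUTCOMES = OUTCOME_COLUMNS[:4]
ARTICULATORY_OUTCOMES = OUTCOME_COLUMNS[4:]

#: continuous outcomes that are log-transformed before scaling; the
#: stiffness index (a ratio of two logged quantities) is scaled untouched
LOG_OUTCOMES = frozenset(
    o for o in OUTCOME_COLUMNS
    if o not in BINARY_OUTCOMES and o != "stiffness_per_s"
)

FAMILY_ALPHA = 0.05
POA_LEVELS = ("pa", "ta", "ka")


@dataclass
class ModelComparison:
    """One likelihood-ratio model comparison with its multiplicity context."""

    outcome: str
    comparison: str  # "interaction DBS x POA", "main DBS", ...
    chi_sq: float
    df: int
    p_value: float
    alpha_corrected: float
    significant: bool
    coefficients: pd.DataFrame
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError("p_value must lie in [0, 1]")
        if self.df < 1:
            raise DataError("df must be >= 1")


def transform_continuous(values, log: bool = True) -> np.ndarray:
    """Natural log (optional), then z-scaling over the analysis set.

    Standardisation uses the sample SD (denominator n - 1).  The transform
    is monotone, so rank order is preserved; an all-equal vector maps to
    all zeros.

    Raises
    ------
    DataError
        On non-positive values when ``log`` is requested.
    """
    x = np.asarray(values, dtype=float)
    if log:
        if np.any(x <= 0):
            raise DataError("log transform requires strictly positive values")
        x = np.log(x)
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    centred = x - np.mean(x)
    return centred / sd if sd > 0 else centred


def sidak_alpha(alpha_family: float, m: int, digits: int | None = 4) -> float:
    """Dunn-Šidák per-test level 1 - (1 - alpha)^(1/m).

    Reported rounded to 4 decimals by default (``digits=None`` for the
    exact value).  Strictly decreasing in m; m = 1 returns the family
    level unchanged.
    """
    if not 0.0 < alpha_family < 1.0:
        raise ConfigError("alpha_family must lie strictly between 0 and 1")
    if m < 1:
        raise ConfigError("m must be a positive count")
    alpha = 1.0 - (1.0 - alpha_family) ** (1.0 / m)
    return alpha if digits is None else round(alpha, digits)


# ---------------------------------------------------------------------------
# design matrices (deviation / sum-to-zero coding, built by hand so the
# coding is explicit and testable)


def _deviation_codes(series: pd.Series, levels) -> tuple[np.ndarray, list[str]]:
    """Sum-coded columns for a factor: one column per non-reference level,
    +1 on that level, -1 on the last (reference) level, 0 elsewhere."""
    levels = list(levels)
    cols, names = [], []
    ref = levels[-1]
    for lev in levels[:-1]:
        col = np.where(series == lev, 1.0, np.where(series == ref, -1.0, 0.0))
        cols.append(col)
        names.append(f"{series.name}[{lev}]")
    return np.column_stack(cols), names


def _build_design(
    df: pd.DataFrame,
    dbs_levels,
    with_poa: bool = True,
    with_interaction: bool = True,
    with_dbs: bool = True,
    dbs_column: str = "dbs",
):
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    dbs_mat, dbs_names = _deviation_codes(
        df[dbs_column].rename("DBS"), dbs_levels
    )
    if with_dbs:
        cols.append(dbs_mat)
        names.extend(dbs_names)
    if with_poa:
        poa_mat, poa_names = _deviation_codes(
            df["syllable"].rename("POA"), POA_LEVELS
        )
        cols.append(poa_mat)
        names.extend(poa_names)
        if with_interaction and with_dbs:
            for j, dn in enumerate(dbs_names):
                for k, pn in enumerate(poa_names):
                    cols.append(dbs_mat[:, j] * poa_mat[:, k])
                    names.append(f"{dn}:{pn}")
    cyc = df["cycle_position"].to_numpy(dtype=float)
    cols.append(cyc - cyc.mean())
    names.append("cycle_position_c")
    return np.column_stack(cols), names


def _response(df: pd.DataFrame, outcome: str, family: str) -> np.ndarray:
    y = df[outcome].to_numpy(dtype=float)
    if family == "binomial":
        return y
    return transform_continuous(y, log=outcome in LOG_OUTCOMES)


def _fit(family: str, X, y, groups, names) -> MixedFitResult:
    if family == "gaussian":
        return fit_lmm(X, y, groups, exog_names=names)
    if family == "binomial":
        return fit_logit_glmm(X, y, groups, exog_names=names)
    raise ConfigError(f"unknown family {family!r}")


def family_for(outcome: str) -> str:
    return "binomial" if outcome in BINARY_OUTCOMES else "gaussian"


def fit_and_compare(
    table: pd.DataFrame,
    outcome: str,
    family: str | None = None,
    comparison: tuple[str, str] = ("OFF", "ON"),
    alpha_family: float = FAMILY_ALPHA,
    m: int = 1,
) -> list[ModelComparison]:
    """LRT model selection for one outcome and one DBS contrast.

    Fits the full model (DBS x POA interaction + centred cycle position +
    speaker random intercept) and tests the interaction against the
    additive model.  If the interaction is not significant at the
    Šidák-corrected alpha, additionally tests the DBS main effect against
    the model without DBS.  Returns the comparisons in that order; each
    carries the coefficient table of its full model and a convergence flag
    (non-convergence is flagged, never silent).
    """
    family = family or family_for(outcome)
    sub = table[table["dbs"].isin(comparison)].reset_index(drop=True)
    if sub["dbs"].nunique() != 2:
        raise DataError(
            f"both DBS levels {comparison} must be present in the table"
        )
    if sub[outcome].isna().any():
        raise DataError(f"outcome {outcome} contains missing values")
    y = _response(sub, outcome, family)
    groups = sub["speaker"].to_numpy()
    alpha = sidak_alpha(alpha_family, m)

    X_full, n_full = _build_design(sub, comparison)
    X_add, n_add = _build_design(sub, comparison, with_interaction=False)
    fit_full = _fit(family, X_full, y, groups, n_full)
    fit_add = _fit(family, X_add, y, groups, n_add)
    chi, p = likelihood_ratio_test(fit_full, fit_add, df=2)
    results = [
        ModelComparison(
            outcome=outcome,
            comparison="interaction DBS x POA",
            chi_sq=chi,
            df=2,
            p_value=p,
            alpha_corrected=alpha,
            significant=p < alpha,
            coefficients=fit_full.summary_frame(),
            converged=fit_full.converged and fit_add.converged,
        )
    ]
    if not results[0].significant:
        X_nodbs, n_nodbs = _build_design(
            sub, comparison, with_interaction=False, with_dbs=False
        )
        fit_nodbs = _fit(family, X_nodbs, y, groups, n_nodbs)
        chi, p = likelihood_ratio_test(fit_add, fit_nodbs, df=1)
        results.append(
            ModelComparison(
                outcome=outcome,
                comparison="main DBS",
                chi_sq=chi,
                df=1,
                p_value=p,
                alpha_corrected=alpha,
                significant=p < alpha,
                coefficients=fit_add.summary_frame(),
                converged=fit_add.converged and fit_nodbs.converged,
            )
        )
    return results


def order_effect_analysis(
    table: pd.DataFrame,
    outcome: str,
    family: str | None = None,
    comparison: tuple[str, str] = ("OFF", "ON"),
    alpha_family: float = FAMILY_ALPHA,
    m: int = 1,
) -> list[ModelComparison]:
    """Exploratory covariate analysis of the stimulation order.

    Starts from the additive model (no DBS x POA interaction).  For the
    control-vs-OFF contrast, tests whether splitting the patient level by
    order — {control, OFF (OFF-ON), OFF (ON-OFF)} — improves on the
    two-level DBS factor (df = 1).  For OFF-vs-ON, tests the
    order x DBS interaction and then, if that is not significant, the
    order main effect.  All results are flagged exploratory.
    """
    family = family or family_for(outcome)
    sub = table[table["dbs"].isin(comparison)].reset_index(drop=True)
    orders = sub.loc[sub["dbs"] != "control", "dbs_order"].unique()
    orders = [o for o in orders if o]
    if len(orders) < 2:
        warnings.warn(
            "only one DBS order group present; order-effect analysis skipped",
            stacklevel=2,
        )
        return []
    y = _response(sub, outcome, family)
    groups = sub["speaker"].to_numpy()
    alpha = sidak_alpha(alpha_family, m)
    note = "exploratory"
    results: list[ModelComparison] = []

    if "control" in comparison:
        grp = np.where(
            sub["dbs"] == "control", "control",
            "OFF(" + sub["dbs_order"].astype(str) + ")",
        )
        sub3 = sub.assign(dbs3=grp)
        levels3 = ["OFF(OFF-ON)", "OFF(ON-OFF)", "control"]
        X3, n3 = _build_design(
            sub3, levels3, with_interaction=False, dbs_column="dbs3"
        )
        X2, n2 = _build_design(sub, comparison, with_interaction=False)
        fit3 = _fit(family, X3, y, groups, n3)
        fit2 = _fit(family, X2, y, groups, n2)
        chi, p = likelihood_ratio_test(fit3, fit2, df=1)
        results.append(
            ModelComparison(
                outcome=outcome, comparison="DBS order split of OFF",
                chi_sq=chi, df=1, p_value=p, alpha_corrected=alpha,
                significant=p < alpha, coefficients=fit3.summary_frame(),
                converged=fit3.converged and fit2.converged, note=note,
            )
        )
        return results

    # OFF vs ON within patients: order x DBS interaction, then order main
    ord_mat, ord_names = _deviation_codes(
        sub["dbs_order"].rename("order"), ["OFF-ON", "ON-OFF"]
    )
    dbs_mat, _ = _deviation_codes(sub["dbs"].rename("DBS"), comparison)

    def with_extra(extra_cols, extra_names):
        X, names = _build_design(sub, comparison, with_interaction=False)
        if extra_cols is not None:
            X = np.column_stack([X, extra_cols])
            names = names + extra_names
        return X, names

    inter = ord_mat[:, 0] * dbs_mat[:, 0]
    X_int, n_int = with_extra(
        np.column_stack([ord_mat, inter[:, None]]),
        ord_names + [f"DBS:{ord_names[0]}"],
    )
    X_ord, n_ord = with_extra(ord_mat, ord_names)
    X_base, n_base = with_extra(None, None)
    fit_int = _fit(family, X_int, y, groups, n_int)
    fit_ord = _fit(family, X_ord, y, groups, n_ord)
    chi, p = likelihood_ratio_test(fit_int, fit_ord, df=1)
    results.append(
        ModelComparison(
            outcome=outcome, comparison="interaction DBS x order",
            chi_sq=chi, df=1, p_value=p, alpha_corrected=alpha,
            significant=p < alpha, coefficients=fit_int.summary_frame(),
            converged=fit_int.converged and fit_ord.converged, note=note,
        )
    )
    if not results[-1].significant:
        fit_base = _fit(family, X_base, y, groups, n_base)
        chi, p = likelihood_ratio_test(fit_ord, fit_base, df=1)
        results.append(
            ModelComparison(
                outcome=outcome, comparison="main DBS order",
                chi_sq=chi, df=1, p_value=p, alpha_corrected=alpha,
                significant=p < alpha, coefficients=fit_ord.summary_frame(),
                converged=fit_ord.converged and fit_base.converged, note=note,
            )
        )
    return results


def summarize_cohort(
    subject_table: pd.DataFrame, group_col: str | None = None
) -> pd.DataFrame:
    """Mean and sample SD (denominator n - 1) per numeric column.

    With ``group_col``, statistics are computed per group.  Columns with a
    single observation report a missing SD.  Values are rounded to 2
    decimals, the precision used for cohort summary tables.
    """
    numeric = subject_table.select_dtypes(include=[np.number])
    if group_col is not None:
        numeric = numeric.join(subject_table[group_col])
        out = numeric.groupby(group_col).agg(["mean", "std"])
    else:
        out = numeric.agg(["mean", "std"]).T
        out.columns = ["mean", "std"]
    return out.round(2)
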