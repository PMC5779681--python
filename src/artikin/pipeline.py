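"""End-to-end pipeline: simulate -> select -> landmark -> measure -> model.

Each stage logs token counts into a reconciling ledger (trains generated,
cycles annotated, cycles selected, tokens measured, tokens modelled); any
stage error aborts with the stage name and the offending trial id.  Given
a fixed seed the whole run, including every output file, is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .acoustics import compute_acoustic_measures, select_cycles
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .core import ArtikinError, DataError
from .io import RunConfig, trajectory_filename, write_annotations, write_trajectory
from .kinematics import measure_cycles
from .stats import (
    ACOUSTIC_OUTCOMES,
    ARTICULATORY_OUTCOMES,
    ModelComparison,
    fit_and_compare,
    order_effect_analysis,
)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "build_token_table",
           "run_stats", "format_report", "COMPARISONS"]

log = logging.getLogger("artikin")

COMPARISONS = (("control", "OFF"), ("OFF", "ON"))


class PipelineError(ArtikinError):
    """A stage failed; the message names the stage and the trial."""

    def __init__(self, stage: str, trial_id: str | None, cause: Exception):
        self.stage = stage
        self.trial_id = trial_id
        self.cause = cause
        where = f" (trial {trial_id})" if trial_id else ""
        super().__init__(f"stage '{stage}'{where}: {cause}")


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    tokens: pd.DataFrame
    results: list[ModelComparison]
    order_results: list[ModelComparison]
    report: str
    ledger: dict


def _cohort_config(config: RunConfig) -> CohortConfig:
    factory = (CohortConfig.calibrated if config.calibration == "calibrated"
               else CohortConfig.null)
    return factory(
        sample_rate=config.sample_rate,
        noise_sd=config.noise_sd,
        n_cycles=config.n_cycles,
        n_reps=config.n_reps,
        n_controls=config.n_controls,
        n_patients=config.n_patients,
        injected_effects=dict(config.injected_effects),
        order_effects=dict(config.order_effects),
    )


def build_token_table(cohort: SyntheticCohort, config: RunConfig,
                      ledger: dict | None = None) -> pd.DataFrame:
    """Measure every trial: cycle selection, acoustics, landmarks, kinematics."""
    ledger = ledger if ledger is not None else {}
    rows = []
    n_cycles_in = 0
    for trial in cohort.trials:
        tid = trial.trial_id
        n_cycles_in += len(trial.cycles)
        try:
            selected = select_cycles(trial.cycles, trial_id=tid)
        except DataError as e:
            raise PipelineError("cycle-selection", tid, e) from e
        try:
            measured = measure_cycles(
                trial.trajectory, selected,
                cutoff=config.smoothing_cutoff,
                min_peak_velocity=config.min_peak_velocity,
                onset_frac=config.onset_frac,
                noise_floor=config.noise_floor,
            )
        except DataError as e:
            raise PipelineError("landmark-detection", tid, e) from e
        for cyc, (lm, kin) in zip(selected, measured):
            try:
                ac = compute_acoustic_measures(
                    cyc, contiguous_only=config.contiguous_voicing
                )
            except DataError as e:
                raise PipelineError("acoustic-measures", tid, e) from e
            rows.append(
                {
                    "speaker": trial.speaker,
                    "dbs": trial.dbs,
                    "dbs_order": trial.dbs_order or "",
                    "syllable": trial.syllable,
                    "rep": trial.rep,
                    "cycle_position": cyc.cycle_index,
                    "syllable_duration_ms": ac.syllable_duration_ms,
                    "voicing_ratio": ac.voicing_ratio,
                    "voicing_during_closure": int(ac.voicing_during_closure),
                    "frication_during_closure": int(ac.frication_during_closure),
                    "accel_phase_ms": kin.accel_phase_ms,
                    "decel_phase_ms": kin.decel_phase_ms,
                    "displacement_mm": kin.displacement_mm,
                    "peak_velocity_mm_s": kin.peak_velocity_mm_s,
                    "stiffness_per_s": kin.stiffness_per_s,
                }
            )
    tokens = pd.DataFrame(rows)
    ledger.update(
        trains_generated=len(cohort.trials),
        cycles_annotated=n_cycles_in,
        cycles_selected=len(cohort.trials) * 10,
        tokens_measured=len(tokens),
    )
    return tokens


def run_stats(tokens: pd.DataFrame, alpha_family: float = 0.05,
              exploratory_order: bool = True):
    """Run the full model-selection procedure on a token table.

    Both DBS contrasts, all nine outcomes, with family sizes m = 4
    (acoustic) and m = 5 (articulatory) for the Šidák correction; the
    exploratory order-effect comparisons are computed separately.
    """
    results: list[ModelComparison] = []
    order_results: list[ModelComparison] = []
    for comparison in COMPARISONS:
        for outcomes, m in ((ACOUSTIC_OUTCOMES, 4), (ARTICULATORY_OUTCOMES, 5)):
            for outcome in outcomes:
                try:
                    res = fit_and_compare(
                        tokens, outcome, comparison=comparison,
                        alpha_family=alpha_family, m=m,
                    )
                except DataError as e:
                    raise PipelineError("statistics", f"{comparison}/{outcome}", e)
                for r in res:
                    r.note = f"{comparison[0]} vs {comparison[1]}"
                results.extend(res)
                if exploratory_order:
                    ores = order_effect_analysis(
                        tokens, outcome, comparison=comparison,
                        alpha_family=alpha_family, m=m,
                    )
                    for r in ores:
                        r.note = f"exploratory; {comparison[0]} vs {comparison[1]}"
                    order_results.extend(ores)
    return results, order_results


def results_frame(results: list[ModelComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": r.outcome,
            "contrast": r.note,
            "comparison": r.comparison,
            "chi_sq": round(r.chi_sq, 4),
            "df": r.df,
            "p_value": float(f"{r.p_value:.6g}"),
            "alpha_corrected": r.alpha_corrected,
            "significant": r.significant,
            "converged": r.converged,
        }
        for r in results
    )


def group_means(tokens: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD per outcome x group x syllable, table-style."""
    from .cohort import OUTCOME_COLUMNS

    g = tokens.groupby(["dbs", "syllable"])[list(OUTCOME_COLUMNS)]
    return g.agg(["mean", "std"]).round(2)


def format_report(tokens: pd.DataFrame, results: list[ModelComparison],
                  order_results: list[ModelComparison], ledger: dict) -> str:
    lines = ["DDK articulatory-acoustic analysis report", "=" * 42, ""]
    lines.append("Token ledger: " + ", ".join(
        f"{k}={v}" for k, v in ledger.items()))
    lines.append("")
    means = group_means(tokens)
    for outcome in [c for c in tokens.columns if c in means.columns.levels[0]]:
        lines.append(f"--- {outcome} ---")
        block = means[outcome].unstack(level=0)
        lines.append(block.to_string())
        for r in results:
            if r.outcome == outcome:
                verdict = "significant" if r.significant else "n.s."
                lines.append(
                    f"  [{r.note}] {r.comparison}: chi2({r.df}) = "
                    f"{r.chi_sq:.1f}, p = {r.p_value:.4g} "
                    f"(alpha_corr = {r.alpha_corrected}) -> {verdict}"
                )
        lines.append("")
    if order_results:
        lines.append("Exploratory DBS-order comparisons")
        lines.append("-" * 33)
        for r in order_results:
            verdict = "significant" if r.significant else "n.s."
            lines.append(
                f"  {r.outcome} [{r.note}] {r.comparison}: chi2({r.df}) = "
                f"{r.chi_sq:.1f}, p = {r.p_value:.4g} -> {verdict}"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full chain and (optionally) write the results bundle.

    Writes ``annotations.csv``, ``tokens.csv``, ``results.csv``,
    ``order_results.csv``, ``report.txt`` and ``config.yaml`` into
    ``out_dir`` (plus per-trial trajectory TSVs under ``trajectories/``
    when configured); outputs are byte-identical across runs with the same
    config and seed.
    """
    ledger: dict = {}
    try:
        cohort = generate_cohort(_cohort_config(config), config.seed)
    except ArtikinError as e:
        raise PipelineError("simulate", None, e) from e
    log.info("simulated %d trials", len(cohort.trials))

    tokens = build_token_table(cohort, config, ledger)
    log.info("measured %d tokens", len(tokens))

    results, order_results = run_stats(tokens, alpha_family=config.alpha_family)
    ledger["tokens_modelled"] = int(
        tokens["dbs"].isin(("control", "OFF", "ON")).sum()
    )
    ledger["model_comparisons"] = len(results)
    report = format_report(tokens, results, order_results, ledger)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_annotations(cohort.annotation_table(), out / "annotations.csv")
        tokens.to_csv(out / "tokens.csv", index=False)
        results_frame(results).to_csv(out / "results.csv", index=False)
        results_frame(order_results).to_csv(out / "order_results.csv", index=False)
        (out / "report.txt").write_text(report)
        config.to_yaml(out / "config.yaml")
        cohort.subjects.to_csv(out / "subjects.csv", index=False)
        if config.write_trajectories:
            tdir = out / "trajectories"
            tdir.mkdir(exist_ok=True)
            for tr in cohort.trials:
                write_trajectory(
                    tr.trajectory,
                    tdir / trajectory_filename(tr.speaker, tr.dbs,
                                               tr.syllable, tr.rep),
                )
    return PipelineResult(cohort, tokens, results, order_results, report, ledger)
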