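"""Cycle selection and acoustic variables (1)-(4) from annotation tiers.

The acoustic stage consumes manually-annotated (or synthetically generated)
interval tiers; it performs no audio signal processing.  Of each
syllable-repetition train, the first three cycles are discarded to avoid
prosodic-boundary effects and the next ten are analysed, re-indexed 1-10
so that within-train position can enter the models as a centred covariate.
"""

from __future__ import annotations

from dataclasses import replace

from .core import (
    AcousticRecord,
    AnnotationError,
    InsufficientDataError,
    SyllableCycle,
)

__all__ = ["select_cycles", "compute_acoustic_measures", "VOICING_THRESHOLD_MS"]

#: Voicing persisting strictly longer than this during the closure counts as
#: voicing-during-closure; anything up to and including 20 ms is attributed
#: to coarticulation with the preceding vowel.
VOICING_THRESHOLD_MS = 20.0

N_DISCARD = 3
N_KEEP = 10


def select_cycles(
    cycles: list[SyllableCycle], trial_id: str | None = None
) -> list[SyllableCycle]:
    """Discard the first three cycles and keep the following ten.

    Cycles 4-13 (1-based) are returned in order, re-indexed 1-10 for use as
    the cycle-position covariate.

    Raises
    ------
    InsufficientDataError
        If fewer than 13 cycles are available; the message names the trial
        when ``trial_id`` is given.
    """
    needed = N_DISCARD + N_KEEP
    if len(cycles) < needed:
        where = f" in trial {trial_id}" if trial_id else ""
        raise InsufficientDataError(
            f"need at least {needed} syllable cycles{where}, "
            f"got {len(cycles)}"
        )
    kept = cycles[N_DISCARD : N_DISCARD + N_KEEP]
    return [replace(c, cycle_index=i + 1) for i, c in enumerate(kept)]


def _merge_spans(spans):
    """Union of possibly-overlapping (start, end) spans."""
    merged = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlap(span, lo, hi):
    return max(0.0, min(span[1], hi) - max(span[0], lo))


def compute_acoustic_measures(
    cycle: SyllableCycle, contiguous_only: bool = False
) -> AcousticRecord:
    """Compute variables (1)-(4) for one syllable cycle.

    * syllable duration: cycle end - cycle start (ms);
    * voicing-to-syllable ratio: total voiced time within the cycle
      (vowel included) over the duration, in [0, 1];
    * voicing-during-closure: True iff voiced time within the closure
      interval exceeds 20 ms *strictly* (exactly 20 ms does not count);
      voiced spans within the closure are summed by default, or only the
      longest contiguous span is considered with ``contiguous_only``;
    * frication-during-closure: the manual binary label, passed through
      unthresholded.

    Raises
    ------
    AnnotationError
        If a voiced span extends beyond the cycle.
    """
    dur = cycle.duration_ms
    spans = _merge_spans(cycle.voiced_spans)
    for s, e in spans:
        if s < cycle.cycle_start_ms - 1e-9 or e > cycle.cycle_end_ms + 1e-9:
            raise AnnotationError(
                f"voiced span ({s:.1f}, {e:.1f}) ms extends beyond cycle "
                f"({cycle.cycle_start_ms:.1f}, {cycle.cycle_end_ms:.1f}) ms"
            )
    voiced_total = sum(e - s for s, e in spans)
    clo = (cycle.closure_start_ms, cycle.closure_end_ms)
    overlaps = [_overlap(sp, *clo) for sp in spans]
    voiced_closure = max(overlaps, default=0.0) if contiguous_only else sum(overlaps)
    return AcousticRecord(
        syllable_duration_ms=float(dur),
        voicing_ratio=float(min(voiced_total / dur, 1.0)),
        voicing_during_closure=bool(voiced_closure > VOICING_THRESHOLD_MS),
        frication_during_closure=bool(cycle.frication_flag),
    )
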