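"""File formats and run configuration.

Everything on disk is plain text: trajectories as two-column TSV
(``time_ms<TAB>position_mm``), annotation tiers and token tables as CSV,
configuration as YAML.  All timestamps are absolute trial time in ms.
An optional Praat TextGrid exporter/importer is provided for
interoperability with phonetics tooling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigError, FormatError, SyllableCycle, Trajectory

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_annotations",
    "write_annotations",
    "cycles_from_annotations",
    "write_textgrid",
    "read_textgrid",
    "trajectory_filename",
]

TRAJECTORY_HEADER = "time_ms\tposition_mm"

ANNOTATION_COLUMNS = [
    "speaker", "condition", "order", "syllable", "rep", "cycle_index",
    "cycle_start_ms", "cycle_end_ms", "closure_start_ms", "closure_end_ms",
    "vowel_start_ms", "vowel_end_ms", "voiced_ms_in_closure", "frication_flag",
]


def trajectory_filename(speaker: str, condition: str, syllable: str,
                        rep: int) -> str:
    return f"{speaker}_{condition}_{syllable}_{rep}.tsv"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as TSV; round-trips losslessly to float precision."""
    with open(path, "w") as fh:
        fh.write(TRAJECTORY_HEADER + "\n")
        for t, x in zip(traj.times.tolist(), traj.positions.tolist()):
            fh.write(f"{t!r}\t{x!r}\n")


def read_trajectory(path, sensor: str = "unknown") -> Trajectory:
    """Read a trajectory TSV written by :func:`write_trajectory`.

    Raises
    ------
    FormatError
        On a malformed header or row (with its line number), an empty
        file, out-of-order rows, or a non-uniform time step (tolerance
        1e-6 ms).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    if lines[0] != TRAJECTORY_HEADER:
        raise FormatError(
            f"{path}:1: expected header {TRAJECTORY_HEADER!r}, got "
            f"{lines[0]!r}"
        )
    times, positions = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            times.append(float(parts[0]))
            positions.append(float(parts[1]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value")
    if len(times) < 2:
        raise FormatError(f"{path}: needs at least 2 samples")
    times = np.asarray(times)
    steps = np.diff(times)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 3  # +2 header/1-based, +1 second row
        raise FormatError(f"{path}:{bad}: time stamps not strictly increasing")
    step = float(np.mean(steps))
    if np.max(np.abs(steps - step)) > 1e-6:
        raise FormatError(f"{path}: non-uniform time step beyond 1e-6 ms")
    return Trajectory(sensor, times, np.asarray(positions), 1000.0 / step)


def write_annotations(table: pd.DataFrame, path) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"annotation table missing columns {missing}")
    table.to_csv(path, index=False, columns=ANNOTATION_COLUMNS)


def read_annotations(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False,
                        dtype={"order": str, "speaker": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return table


def cycles_from_annotations(rows: pd.DataFrame) -> list[SyllableCycle]:
    """Rebuild SyllableCycle objects for one trial from annotation rows.

    The voiced tier is reconstructed from the schema's summary: the vowel
    interval plus a voiced span of ``voiced_ms_in_closure`` at the start of
    the closure (voicing carrying over from the preceding vowel).
    """
    cycles = []
    for row in rows.sort_values("cycle_index").itertuples(index=False):
        spans = []
        if row.voiced_ms_in_closure > 0:
            spans.append(
                (row.closure_start_ms,
                 row.closure_start_ms + row.voiced_ms_in_closure)
            )
        spans.append((row.vowel_start_ms, row.vowel_end_ms))
        cycles.append(
            SyllableCycle(
                cycle_index=int(row.cycle_index),
                cycle_start_ms=row.cycle_start_ms,
                cycle_end_ms=row.cycle_end_ms,
                closure_start_ms=row.closure_start_ms,
                closure_end_ms=row.closure_end_ms,
                vowel_start_ms=row.vowel_start_ms,
                vowel_end_ms=row.vowel_end_ms,
                voiced_spans=spans,
                frication_flag=bool(row.frication_flag),
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Every threshold carries its default here; the file representation is
    YAML and round-trips losslessly.
    """

    seed: int = 1
    calibration: str = "calibrated"  # "calibrated" or "null"
    sample_rate: float = 250.0       # Hz
    noise_sd: float = 0.1            # mm, additive position noise
    smoothing_cutoff: float = 30.0   # Hz, zero-phase low-pass
    min_peak_velocity: float = 5.0   # mm/s, below this: no gesture
    onset_frac: float = 0.01         # landmark sub-threshold, fraction of peak
    noise_floor: float = 2.0         # mm/s, landmark velocity noise floor
    n_cycles: int = 13               # simulated cycles per train
    n_reps: int = 2
    n_controls: int = 12
    n_patients: int = 12
    alpha_family: float = 0.05
    contiguous_voicing: bool = False
    write_trajectories: bool = False
    injected_effects: dict = field(default_factory=dict)
    order_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calibration not in ("calibrated", "null"):
            raise ConfigError(
                f"calibration must be 'calibrated' or 'null', "
                f"got {self.calibration!r}"
            )
        if not 0.0 < self.alpha_family < 1.0:
            raise ConfigError("alpha_family must lie strictly in (0, 1)")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# TextGrid (Praat long text format), minimal


def write_textgrid(cycles: list[SyllableCycle], path,
                   total_duration_ms: float | None = None) -> None:
    """Export annotation tiers of one trial as a Praat TextGrid.

    Interval tiers ``cycle``, ``closure``, ``vowel``, ``voicing``; times in
    seconds as Praat expects.
    """
    if total_duration_ms is None:
        total_duration_ms = max(c.cycle_end_ms for c in cycles)
    xmax = total_duration_ms / 1000.0

    def tier_intervals(name):
        if name == "cycle":
            return [(c.cycle_start_ms, c.cycle_end_ms, str(c.cycle_index))
                    for c in cycles]
        if name == "closure":
            return [(c.closure_start_ms, c.closure_end_ms, "clo")
                    for c in cycles]
        if name == "vowel":
            return [(c.vowel_start_ms, c.vowel_end_ms, "a") for c in cycles]
        spans = [s for c in cycles for s in c.voiced_spans]
        return [(s, e, "v") for s, e in sorted(spans)]

    def with_gaps(marked, xmax_s):
        out, cursor = [], 0.0
        for s, e, lab in marked:
            s_s, e_s = s / 1000.0, e / 1000.0
            if s_s > cursor + 1e-9:
                out.append((cursor, s_s, ""))
            out.append((s_s, e_s, lab))
            cursor = e_s
        if cursor < xmax_s - 1e-9:
            out.append((cursor, xmax_s, ""))
        return out

    tiers = ["cycle", "closure", "vowel", "voicing"]
    with open(path, "w") as fh:
        fh.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
        fh.write(f"xmin = 0\nxmax = {xmax!r}\ntiers? <exists>\n")
        fh.write(f"size = {len(tiers)}\nitem []:\n")
        for ti, name in enumerate(tiers, start=1):
            ivals = with_gaps(tier_intervals(name), xmax)
            fh.write(f"    item [{ti}]:\n")
            fh.write('        class = "IntervalTier"\n')
            fh.write(f'        name = "{name}"\n')
            fh.write(f"        xmin = 0\n        xmax = {xmax!r}\n")
            fh.write(f"        intervals: size = {len(ivals)}\n")
            for ii, (s, e, lab) in enumerate(ivals, start=1):
                fh.write(f"        intervals [{ii}]:\n")
                fh.write(f"            xmin = {s!r}\n")
                fh.write(f"            xmax = {e!r}\n")
                fh.write(f'            text = "{lab}"\n')


def read_textgrid(path) -> dict[str, list[tuple[float, float, str]]]:
    """Parse interval tiers from a (long-format) TextGrid.

    Returns a mapping tier name -> list of (start_ms, end_ms, label) for
    non-empty labels.
    """
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    name = None
    xmin = xmax = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("name ="):
                name = line.split("=", 1)[1].strip().strip('"')
                tiers[name] = []
            elif line.startswith("xmin =") and name is not None:
                xmin = float(line.split("=", 1)[1])
            elif line.startswith("xmax =") and name is not None:
                xmax = float(line.split("=", 1)[1])
            elif line.startswith("text =") and name is not None:
                label = line.split("=", 1)[1].strip().strip('"')
                if label and xmin is not None and xmax is not None:
                    tiers[name].append((xmin * 1000.0, xmax * 1000.0, label))
    if not tiers:
        raise FormatError(f"{path}: no interval tiers found")
    return tiers
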