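"""Shared domain types and exceptions.

Conventions used throughout the package: time is absolute trial time in
milliseconds, positions in millimetres, velocities in mm/s, accelerations in
mm/s^2, and natural frequencies (the abstract "stiffness" control parameter)
in 1/s. Sample indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArtikinError",
    "ParameterError",
    "ConfigError",
    "DataError",
    "FormatError",
    "AnnotationError",
    "InsufficientDataError",
    "NoGestureError",
    "UndefinedStiffnessError",
    "TruncationWarning",
    "Trajectory",
    "DerivedTraces",
    "GestureLandmarks",
    "KinematicRecord",
    "SyllableCycle",
    "AcousticRecord",
]


class ArtikinError(Exception):
    """Base class for all package errors."""


class ParameterError(ArtikinError, ValueError):
    """A numeric parameter violates its contract (e.g. non-positive omega)."""


class ConfigError(ArtikinError, ValueError):
    """A configuration value is invalid (probabilities outside [0, 1], ...)."""


class DataError(ArtikinError, ValueError):
    """Input data violate a contract (non-positive values before log, ...)."""


class FormatError(DataError):
    """A file does not conform to the expected on-disk schema."""


class AnnotationError(DataError):
    """An annotation tier is internally inconsistent."""


class InsufficientDataError(DataError):
    """Too few samples or cycles to perform the requested operation."""


class NoGestureError(DataError):
    """No movement above the noise floor in the landmark search window."""


class UndefinedStiffnessError(DataError):
    """Displacement below resolution; the peak-velocity ratio is undefined."""


class TruncationWarning(UserWarning):
    """The cycle period is too short for the gesture's natural frequency.

    The closing gesture never approaches its target within 5% before the
    next gesture takes over.  This is the truncation regime under study,
    so it is reported as a warning, never an error.
    """


@dataclass
class Trajectory:
    """One articulator channel sampled uniformly in time.

    Attributes
    ----------
    sensor : str
        Articulator label, e.g. ``"lower-lip"``, ``"tongue-tip"``,
        ``"tongue-dorsum"``.
    times : ndarray
        Absolute trial time in ms on a strictly increasing uniform grid.
    positions : ndarray
        Vertical position in mm, finite.
    sample_rate : float
        Samples per second; the grid step is ``1000 / sample_rate`` ms.
    """

    sensor: str
    times: np.ndarray
    positions: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.times.ndim != 1 or self.times.shape != self.positions.shape:
            raise DataError("times and positions must be 1-D and equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            step = 1000.0 / self.sample_rate
            if np.any(steps <= 0):
                raise DataError("times must be strictly increasing")
            if np.max(np.abs(steps - step)) > 1e-6:
                raise DataError(
                    "times must be a uniform grid with step 1000/sample_rate"
                )
        if not np.all(np.isfinite(self.positions)):
            raise DataError("positions must be finite")

    @property
    def duration_ms(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.sensor == other.sensor
            and self.sample_rate == other.sample_rate
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.positions, other.positions)
        )


@dataclass
class DerivedTraces:
    """Smoothed position with velocity and acceleration on the same grid."""

    times: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    sample_rate: float


@dataclass
class GestureLandmarks:
    """Onset, peak-velocity, and target timestamps of one consonantal gesture.

    All timestamps are absolute trial time in ms; ``onset_pos`` and
    ``target_pos`` are the articulator positions (mm) at onset and target.
    """

    onset_ms: float
    pvel_ms: float
    target_ms: float
    onset_pos: float
    target_pos: float

    def __post_init__(self) -> None:
        if not (self.onset_ms < self.pvel_ms < self.target_ms):
            raise DataError(
                "landmarks must be ordered onset < peak velocity < target "
                f"(got {self.onset_ms}, {self.pvel_ms}, {self.target_ms})"
            )


@dataclass
class KinematicRecord:
    """Articulatory variables of one consonantal gesture.

    accel_phase_ms
        Onset to peak velocity.
    decel_phase_ms
        Peak velocity to target.
    displacement_mm
        |position(target) - position(onset)|.
    peak_velocity_mm_s
        |velocity| at the peak-velocity landmark.
    stiffness_per_s
        peak velocity / displacement, the kinematic stiffness index.
    """

    accel_phase_ms: float
    decel_phase_ms: float
    displacement_mm: float
    peak_velocity_mm_s: float
    stiffness_per_s: float


@dataclass
class SyllableCycle:
    """Annotation intervals for one syllable cycle (CV = stop + vowel).

    The cycle runs from the onset of the consonantal constriction to the
    offset of the following vowel.  ``voiced_spans`` are (start, end) pairs
    in ms; ``frication_flag`` is the manual binary label for turbulent noise
    during the constriction.
    """

    cycle_index: int
    cycle_start_ms: float
    cycle_end_ms: float
    closure_start_ms: float
    closure_end_ms: float
    vowel_start_ms: float
    vowel_end_ms: float
    voiced_spans: list[tuple[float, float]] = field(default_factory=list)
    frication_flag: bool = False

    def __post_init__(self) -> None:
        if not self.cycle_end_ms > self.cycle_start_ms:
            raise AnnotationError("cycle must have positive duration")
        if not self.closure_end_ms > self.closure_start_ms:
            raise AnnotationError("closure must have positive duration")
        if not self.vowel_end_ms > self.vowel_start_ms:
            raise AnnotationError("vowel must have positive duration")
        if self.closure_end_ms > self.vowel_start_ms + 1e-9:
            raise AnnotationError("closure must precede the vowel")

    @property
    def duration_ms(self) -> float:
        return self.cycle_end_ms - self.cycle_start_ms


@dataclass
class AcousticRecord:
    """Acoustic variables of one syllable cycle."""

    syllable_duration_ms: float
    voicing_ratio: float
    voicing_during_closure: bool
    frication_during_closure: bool
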