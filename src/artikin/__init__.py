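"""artikin: articulatory kinematics of fast syllable repetition (DDK) tasks.

A reusable measurement-and-inference chain for articulographic DDK
recordings, with a calibrated synthetic-cohort generator standing in for
patient data: critically damped mass-spring gesture simulation, landmark
detection on velocity/acceleration zero-crossings, the nine standard
acoustic/kinematic syllable variables, and random-intercept mixed-model
inference with likelihood-ratio model selection and Dunn-Šidák
multiplicity control.
"""

from importlib.resources import files as _files

import pandas as _pd

from .acoustics import compute_acoustic_measures, select_cycles
from .cohort import (
    CohortConfig,
    SyntheticCohort,
    generate_cohort,
    simulate_token_table,
)
from .core import (
    AcousticRecord,
    ArtikinError,
    DerivedTraces,
    GestureLandmarks,
    KinematicRecord,
    SyllableCycle,
    Trajectory,
)
from .gesture import (
    AnnotationModel,
    DDKSpec,
    GestureParams,
    apply_modification,
    simulate_ddk_train,
    simulate_gesture,
)
from .io import RunConfig, read_trajectory, write_trajectory
from .kinematics import compute_kinematics, detect_landmarks, smooth_and_differentiate
from .pipeline import PipelineResult, run_pipeline
from .stats import (
    ModelComparison,
    fit_and_compare,
    order_effect_analysis,
    sidak_alpha,
    summarize_cohort,
    transform_continuous,
)

__version__ = "0.1.0"


def load_cohort_characteristics() -> "_pd.DataFrame":
    """The published subject table: 12 patients and 12 matched controls.

    Columns: patient sex/age, disease duration (years), months since
    implantation, and the matched control's sex/age.
    """
    path = _files("artikin").joinpath("data/cohort_characteristics.csv")
    return _pd.read_csv(path)


__all__ = [name for name in dir() if not name.startswith("_")]
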