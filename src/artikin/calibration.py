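"""Published group-level calibration constants for the synthetic cohort.

The study this package emulates reports acoustic and articulatory group
means (and SDs) for three speaker groups — healthy controls, patients with
thalamic stimulation switched off (OFF), and switched on (ON) — for each
place of articulation (/pa/, /ta/, /ka/).  Those printed summary statistics
are the only quantitative trace of the unreleased patient recordings, so
the synthetic-data generator treats them as calibration targets: the
generating parameters of each group x syllable cell are chosen so the
expected values of the simulated variables match the table entries.

Entries are (mean, sd).  Probabilities for the binary variables are group
proportions.  The ON /ka/ peak-velocity mean is not printed in the source
table (only its SD); it is imputed as the OFF mean times 0.723, the average
ON/OFF ratio of the /pa/ and /ta/ cells.
"""

from __future__ import annotations

GROUPS = ("control", "OFF", "ON")
SYLLABLES = ("pa", "ta", "ka")

#: (1) syllable duration in ms, (mean, sd) per (group, syllable)
SYLLABLE_DURATION_MS = {
    ("control", "pa"): (151.0, 15.0), ("OFF", "pa"): (193.0, 55.0), ("ON", "pa"): (221.0, 67.0),
    ("control", "ta"): (163.0, 19.0), ("OFF", "ta"): (217.0, 77.0), ("ON", "ta"): (242.0, 77.0),
    ("control", "ka"): (173.0, 22.0), ("OFF", "ka"): (229.0, 68.0), ("ON", "ka"): (273.0, 81.0),
}

#: (2) voicing-to-syllable ratio, (mean, sd)
VOICING_RATIO = {
    ("control", "pa"): (0.51, 0.11), ("OFF", "pa"): (0.58, 0.17), ("ON", "pa"): (0.60, 0.14),
    ("control", "ta"): (0.57, 0.12), ("OFF", "ta"): (0.62, 0.15), ("ON", "ta"): (0.65, 0.15),
    ("control", "ka"): (0.52, 0.10), ("OFF", "ka"): (0.54, 0.14), ("ON", "ka"): (0.62, 0.15),
}

#: (3) proportion of cycles with voicing during closure
P_VOICING_DURING_CLOSURE = {
    ("control", "pa"): 0.44, ("OFF", "pa"): 0.66, ("ON", "pa"): 0.72,
    ("control", "ta"): 0.48, ("OFF", "ta"): 0.58, ("ON", "ta"): 0.84,
    ("control", "ka"): 0.26, ("OFF", "ka"): 0.38, ("ON", "ka"): 0.53,
}

#: (4) proportion of cycles with frication during closure
P_FRICATION_DURING_CLOSURE = {
    ("control", "pa"): 0.05, ("OFF", "pa"): 0.19, ("ON", "pa"): 0.33,
    ("control", "ta"): 0.65, ("OFF", "ta"): 0.65, ("ON", "ta"): 0.86,
    ("control", "ka"): 0.26, ("OFF", "ka"): 0.57, ("ON", "ka"): 0.75,
}

#: (5) acceleration phase in ms, (mean, sd)
ACCEL_PHASE_MS = {
    ("control", "pa"): (32.0, 5.0), ("OFF", "pa"): (45.0, 23.0), ("ON", "pa"): (59.0, 42.0),
    ("control", "ta"): (30.0, 5.0), ("OFF", "ta"): (46.0, 24.0), ("ON", "ta"): (50.0, 28.0),
    ("control", "ka"): (42.0, 8.0), ("OFF", "ka"): (59.0, 30.0), ("ON", "ka"): (74.0, 37.0),
}

#: (6) deceleration phase in ms, (mean, sd)
DECEL_PHASE_MS = {
    ("control", "pa"): (44.0, 7.0), ("OFF", "pa"): (57.0, 17.0), ("ON", "pa"): (65.0, 24.0),
    ("control", "ta"): (50.0, 9.0), ("OFF", "ta"): (68.0, 26.0), ("ON", "ta"): (74.0, 33.0),
    ("control", "ka"): (47.0, 8.0), ("OFF", "ka"): (60.0, 18.0), ("ON", "ka"): (68.0, 24.0),
}

#: (8) peak velocity in mm/s, (mean, sd); ON /ka/ mean imputed (see module docstring)
PEAK_VELOCITY_MM_S = {
    ("control", "pa"): (95.9, 35.9), ("OFF", "pa"): (120.4, 43.5), ("ON", "pa"): (87.7, 31.7),
    ("control", "ta"): (83.6, 33.4), ("OFF", "ta"): (100.9, 36.0), ("ON", "ta"): (72.4, 29.0),
    ("control", "ka"): (69.9, 31.2), ("OFF", "ka"): (76.7, 29.4), ("ON", "ka"): (55.5, 24.1),
}

#: (7) displacement in mm, (mean, sd) — reference only, not an independent
#: generator knob: with a critically damped gesture truncated at its
#: activation end, displacement follows from amplitude, omega and the
#: activation duration once accel/decel phases and peak velocity are fixed.
DISPLACEMENT_MM = {
    ("control", "pa"): (4.9, 1.9), ("OFF", "pa"): (6.9, 2.9), ("ON", "pa"): (5.8, 2.5),
    ("control", "ta"): (3.9, 1.7), ("OFF", "ta"): (5.6, 2.5), ("ON", "ta"): (4.5, 2.1),
    ("control", "ka"): (4.1, 1.9), ("OFF", "ka"): (5.2, 1.9), ("ON", "ka"): (4.8, 1.9),
}

#: (9) stiffness (peak velocity / displacement), (mean, sd) — reference only
STIFFNESS = {
    ("control", "pa"): (19.5, 1.7), ("OFF", "pa"): (18.1, 4.3), ("ON", "pa"): (16.0, 4.8),
    ("control", "ta"): (21.7, 2.4), ("OFF", "ta"): (19.3, 4.9), ("ON", "ta"): (17.4, 5.4),
    ("control", "ka"): (17.2, 1.8), ("OFF", "ka"): (15.0, 3.1), ("ON", "ka"): (13.4, 3.6),
}
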