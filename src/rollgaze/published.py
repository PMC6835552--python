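"""Reference values from a four-subject smartphone validation experiment.

A prototype infrared smartphone (5-inch display) was held in a fixed stand at
30 cm from a chin-rested subject while the device roll relative to the head
(R-Roll) was set to 0°, 45° and 90°; five fixation targets were shown for
150 frames each.  These printed per-subject numbers serve as inputs for
reproducing the study's summary statistics — the per-frame videos behind
them are not available, so they cannot be recomputed, only aggregated.

``AVERAGE_EYE`` is the conventional average adult kappa offset used in the
roll-error analysis.
"""

from __future__ import annotations

from .geometry import SubjectEyeParams

__all__ = [
    "AVERAGE_EYE",
    "SUBJECT_EYE_OFFSETS",
    "MEASURED_ROLL_DELTA_DEG",
    "GAZE_ERROR_MM",
    "GAZE_ERROR_DEG",
    "subjects",
]

#: Average adult optical/visual-axis offsets (α, β), degrees.
AVERAGE_EYE = SubjectEyeParams(alpha_deg=3.0, beta_deg=1.5)

#: Calibrated |α|, |β| (degrees) for the four subjects.
SUBJECT_EYE_OFFSETS: dict[str, tuple[float, float]] = {
    "01": (1.73, 0.50),
    "02": (1.21, 0.28),
    "03": (1.78, 0.92),
    "04": (2.67, 0.25),
}

#: Measured angular difference (degrees) between roll-compensated and
#: uncompensated PoG estimates, per (subject, R-Roll degrees).
MEASURED_ROLL_DELTA_DEG: dict[tuple[str, float], float] = {
    ("01", 45.0): 1.22,
    ("01", 90.0): 2.08,
    ("02", 45.0): 0.86,
    ("02", 90.0): 1.76,
    ("03", 45.0): 1.36,
    ("03", 90.0): 2.72,
    ("04", 45.0): 1.81,
    ("04", 90.0): 2.78,
}

#: Mean absolute PoG error in mm, keyed by (subject, method, roll_deg).
#: Method 2 compensates with the measured R-Roll; Method 1 assumes roll 0.
GAZE_ERROR_MM: dict[tuple[str, int, float], float] = {
    ("01", 2, 0.0): 5.07, ("01", 2, 45.0): 4.70, ("01", 2, 90.0): 5.05,
    ("01", 1, 0.0): 4.91, ("01", 1, 45.0): 11.11, ("01", 1, 90.0): 15.96,
    ("02", 2, 0.0): 3.73, ("02", 2, 45.0): 4.55, ("02", 2, 90.0): 5.18,
    ("02", 1, 0.0): 3.52, ("02", 1, 45.0): 9.08, ("02", 1, 90.0): 14.39,
    ("03", 2, 0.0): 3.15, ("03", 2, 45.0): 4.77, ("03", 2, 90.0): 4.12,
    ("03", 1, 0.0): 3.14, ("03", 1, 45.0): 11.91, ("03", 1, 90.0): 18.42,
    ("04", 2, 0.0): 7.23, ("04", 2, 45.0): 5.94, ("04", 2, 90.0): 10.05,
    ("04", 1, 0.0): 7.31, ("04", 1, 45.0): 15.44, ("04", 1, 90.0): 24.66,
}

#: Same cells expressed in degrees of visual angle.
GAZE_ERROR_DEG: dict[tuple[str, int, float], float] = {
    ("01", 2, 0.0): 0.96, ("01", 2, 45.0): 0.89, ("01", 2, 90.0): 0.96,
    ("01", 1, 0.0): 0.93, ("01", 1, 45.0): 2.12, ("01", 1, 90.0): 2.75,
    ("02", 2, 0.0): 0.71, ("02", 2, 45.0): 0.86, ("02", 2, 90.0): 0.98,
    ("02", 1, 0.0): 0.67, ("02", 1, 45.0): 1.73, ("02", 1, 90.0): 2.74,
    ("03", 2, 0.0): 0.60, ("03", 2, 45.0): 0.91, ("03", 2, 90.0): 0.78,
    ("03", 1, 0.0): 0.59, ("03", 1, 45.0): 2.27, ("03", 1, 90.0): 3.51,
    ("04", 2, 0.0): 1.38, ("04", 2, 45.0): 1.13, ("04", 2, 90.0): 1.91,
    ("04", 1, 0.0): 1.39, ("04", 1, 45.0): 2.94, ("04", 1, 90.0): 4.69,
}


def subjects() -> list[tuple[str, SubjectEyeParams]]:
    """The four study subjects as ``(id, SubjectEyeParams)`` pairs."""
    return [
        (sid, SubjectEyeParams(alpha_deg=a, beta_deg=b))
        for sid, (a, b) in SUBJECT_EYE_OFFSETS.items()
    ]
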