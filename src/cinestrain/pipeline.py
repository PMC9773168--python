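"""Contour-stack → subject-level measurements.

Glue between the geometric, strain and volumetric layers: given a cine
contour stack (and optionally the subject's anthropometrics), compute the
nine analysis variables — ACS, MCS, BCS, GCS, EDV, ESV, LVEF, ESVi, BSA —
plus BMI, and assemble cohort-level subject tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import volumetrics
from .geometry import polygon_area, polygon_perimeter
from .strain import allocate_regions, global_strain, regional_strain, strain_curve
from .synthetic import ContourStack, SubjectRecord

__all__ = ["measure_stack", "measure_subject", "cohort_table", "ANALYSIS_VARIABLES"]

# the variables every statistical battery runs over
ANALYSIS_VARIABLES = ("ESV", "EDV", "LVEF", "ESVi", "BSA", "ACS", "MCS", "BCS", "GCS")


def measure_stack(stack: ContourStack) -> dict[str, float]:
    """Strain and volume measurements for one cine stack.

    EDV is the slice-summation volume at frame 0 (end diastole); ESV the
    minimum slice-summation volume over the cycle.  Strains come from the
    perimeter curves via the regional peak-of-mean rule.
    """
    spacing = stack.acquisition.slice_spacing_mm
    curves = []
    areas = np.empty((stack.n_slices, stack.n_frames))
    for s, frames in enumerate(stack.contours):
        perims = np.array([polygon_perimeter(c) for c in frames])
        curves.append(strain_curve(perims, slice_index=s))
        areas[s] = [polygon_area(c) for c in frames]

    volumes = np.array([volumetrics.slice_stack_volume(areas[:, t], spacing) for t in range(stack.n_frames)])
    edv = float(volumes[0])
    esv = float(volumes.min())

    alloc = allocate_regions(stack.n_slices)
    regional = regional_strain(curves, alloc)
    return {
        "EDV": edv,
        "ESV": esv,
        "LVEF": volumetrics.lvef(edv, esv),
        "ACS": regional.acs,
        "MCS": regional.mcs,
        "BCS": regional.bcs,
        "GCS": global_strain(curves),
        "n_slices": stack.n_slices,
    }


def measure_subject(
    subject: SubjectRecord,
    stack: ContourStack,
    bsa_method: str = "du_bois",
) -> dict[str, float]:
    """Full variable set for one subject, including body-size indices."""
    m = measure_stack(stack)
    m["BSA"] = volumetrics.bsa(subject.height_cm, subject.weight_kg, bsa_method)
    m["BMI"] = volumetrics.bmi(subject.weight_kg, subject.height_cm / 100.0)
    m["ESVi"] = volumetrics.esvi(m["ESV"], m["BSA"])
    subject.measured = dict(m)
    return m


def cohort_table(
    cohort: list[tuple[SubjectRecord, ContourStack]],
    bsa_method: str = "du_bois",
) -> pd.DataFrame:
    """Measure every subject and return the analysis-ready table.

    One row per subject: identifiers, demographics, inclusion-relevant
    flags, and the measured indices.
    """
    rows = []
    for subject, stack in cohort:
        m = measure_subject(subject, stack, bsa_method)
        rows.append(
            {
                "subject_id": subject.subject_id,
                "sex": subject.sex,
                "age_band": subject.age_band,
                "health": subject.health,
                "age": subject.age,
                "height_cm": subject.height_cm,
                "weight_kg": subject.weight_kg,
                "heart_rate": subject.heart_rate,
                "diabetes": subject.diabetes,
                "smoker": subject.smoker,
                "qualifying_ethnicity": subject.qualifying_ethnicity,
                **m,
            }
        )
    return pd.DataFrame(rows)
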