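"""Volume and anthropometric indices.

LV cavity volumes are obtained by slice summation (Simpson's rule for a
gapped short-axis stack): each slice's enclosed endocardial area is
extruded over the full slice spacing (thickness + gap) and the products
summed.  Ejection fraction, end-systolic volume index, body surface area
and body-mass index follow their standard clinical definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VolumeIndices",
    "slice_stack_volume",
    "lvef",
    "bsa",
    "esvi",
    "bmi",
    "DEFAULT_SLICE_SPACING_MM",
]

# 8 mm slice thickness + 2 mm inter-slice gap
DEFAULT_SLICE_SPACING_MM = 10.0

BSA_METHODS = ("du_bois", "mosteller")


class InvalidCycleError(ValueError):
    """ESV exceeding EDV or other physiologically impossible volume pair."""


@dataclass(frozen=True)
class VolumeIndices:
    """Per-subject volumetric and anthropometric summary.

    edv/esv in ml, lvef in %, esvi in ml/m², bsa in m², bmi in kg/m².
    """

    edv: float
    esv: float
    lvef: float
    esvi: float
    bsa: float
    bmi: float


def slice_stack_volume(areas_mm2, spacing_mm: float = DEFAULT_SLICE_SPACING_MM) -> float:
    """Slice-summation volume in ml from per-slice areas (mm²).

    Sum of area × spacing over slices, converted mm³ → ml.  An empty area
    list gives 0 ml.
    """
    areas = np.asarray(areas_mm2, dtype=float)
    if areas.size and (np.any(~np.isfinite(areas)) or np.any(areas < 0)):
        raise ValueError("slice areas must be finite and non-negative")
    if spacing_mm <= 0:
        raise ValueError(f"slice spacing must be positive, got {spacing_mm}")
    return float(areas.sum() * spacing_mm / 1000.0)


def lvef(edv: float, esv: float) -> float:
    """Left-ventricular ejection fraction, % = 100 (EDV − ESV) / EDV."""
    if edv <= 0:
        raise InvalidCycleError(f"EDV must be positive, got {edv}")
    if esv < 0 or esv > edv:
        raise InvalidCycleError(f"ESV must lie in [0, EDV]; got ESV={esv}, EDV={edv}")
    return 100.0 * (edv - esv) / edv


def bsa(height_cm: float, weight_kg: float, method: str = "du_bois") -> float:
    """Body surface area (m²) from height (cm) and weight (kg).

    ``du_bois``:  0.007184 · W^0.425 · H^0.725  (default — the dominant
    convention for CMR volume indexing).
    ``mosteller``: sqrt(H · W / 3600).
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if method == "du_bois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if method == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA method {method!r}; choose from {BSA_METHODS}")


def esvi(esv: float, bsa_m2: float) -> float:
    """End-systolic volume index, ml/m²."""
    if bsa_m2 <= 0:
        raise ValueError(f"BSA must be positive, got {bsa_m2}")
    if esv < 0:
        raise ValueError(f"ESV must be non-negative, got {esv}")
    return esv / bsa_m2


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, kg/m²."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2
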