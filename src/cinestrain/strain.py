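"""Endocardial circumferential strain from per-frame perimeter lengths.

Strain on one short-axis slice at frame *n* is the fractional change of the
endocardial perimeter relative to its end-diastolic reference length::

    eps_n = (L_n - L_0) / L_0

with frame 0 taken as end diastole.  Slices are grouped base-to-apex into
three ventricular regions (base, mid, apex); the regional strain curve is
the frame-wise mean of the member slices' curves, and the reported regional
value (BCS / MCS / ACS) is the most negative point of that averaged curve,
in percent.  Global circumferential strain (GCS) averages over every slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StrainCurve",
    "RegionAllocation",
    "RegionalStrains",
    "strain_curve",
    "allocate_regions",
    "regional_strain",
    "global_strain",
]

MIN_SLICES = 6
MAX_SLICES = 10


class InvalidMeasurementError(ValueError):
    """Perimeter series unusable for strain (nonpositive or too short)."""


class SliceCountError(ValueError):
    """Total slice count outside the acquisition protocol's 6–10 range."""


@dataclass(frozen=True)
class StrainCurve:
    """Strain time series for one slice.

    Attributes
    ----------
    slice_index : int
        Position in the stack, 0 = most basal.
    eps : np.ndarray
        Dimensionless strain per frame; ``eps[0] == 0`` exactly.
    reference_length : float
        End-diastolic perimeter L0 in mm.
    """

    slice_index: int
    eps: np.ndarray
    reference_length: float

    @property
    def peak(self) -> float:
        """Most negative strain over the cycle (dimensionless)."""
        return float(np.min(self.eps))


@dataclass(frozen=True)
class RegionAllocation:
    """Base/mid/apex slice counts for a stack, ordered base → apex."""

    n_base: int
    n_mid: int
    n_apex: int

    @property
    def total(self) -> int:
        return self.n_base + self.n_mid + self.n_apex

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_base, self.n_mid, self.n_apex)

    def slice_ranges(self) -> dict[str, range]:
        """Slice-index ranges per region for a base-first ordered stack."""
        return {
            "base": range(0, self.n_base),
            "mid": range(self.n_base, self.n_base + self.n_mid),
            "apex": range(self.n_base + self.n_mid, self.total),
        }


@dataclass(frozen=True)
class RegionalStrains:
    """Peak regional and global circumferential strains, in percent."""

    acs: float
    mcs: float
    bcs: float
    gcs: float | None = None


def strain_curve(perimeters: np.ndarray, slice_index: int = 0) -> StrainCurve:
    """Compute the strain curve eps_n = (L_n - L_0)/L_0 for one slice.

    ``perimeters`` holds the endocardial perimeter length (mm) per cine
    frame, frame 0 being end diastole.
    """
    lengths = np.asarray(perimeters, dtype=float)
    if lengths.ndim != 1 or lengths.size < 2:
        raise InvalidMeasurementError("need a 1-D series of >= 2 perimeter lengths")
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise InvalidMeasurementError("perimeter lengths must be finite and positive")
    l0 = lengths[0]
    eps = (lengths - l0) / l0
    return StrainCurve(slice_index=slice_index, eps=eps, reference_length=float(l0))


def allocate_regions(n_slices: int) -> RegionAllocation:
    """Split ``n_slices`` (6–10) into base/mid/apex counts.

    Each region gets ``n_slices // 3``; remainder slices are assigned to the
    base first, then the mid-ventricle.  Over the admissible totals this
    yields per-region counts between 2 and 4:
    6→(2,2,2), 7→(3,2,2), 8→(3,3,2), 9→(3,3,3), 10→(4,3,3).
    """
    if not isinstance(n_slices, (int, np.integer)):
        raise TypeError(f"n_slices must be an integer, got {type(n_slices).__name__}")
    if not (MIN_SLICES <= n_slices <= MAX_SLICES):
        raise SliceCountError(f"n_slices must be in [{MIN_SLICES}, {MAX_SLICES}], got {n_slices}")
    base = mid = apex = n_slices // 3
    rem = n_slices - 3 * base
    if rem >= 1:
        base += 1
    if rem == 2:
        mid += 1
    return RegionAllocation(n_base=base, n_mid=mid, n_apex=apex)


def _stack_eps(curves: list[StrainCurve]) -> np.ndarray:
    if not curves:
        raise InvalidMeasurementError("no strain curves supplied")
    n_frames = {c.eps.size for c in curves}
    if len(n_frames) != 1:
        raise InvalidMeasurementError(f"curves have mismatched frame counts: {sorted(n_frames)}")
    return np.vstack([c.eps for c in curves])


def regional_strain(
    curves: list[StrainCurve],
    alloc: RegionAllocation,
    *,
    peak_of_mean: bool = True,
) -> RegionalStrains:
    """Peak ACS/MCS/BCS (%) from a base-ordered list of slice curves.

    For each region the member curves are averaged frame-wise and the
    minimum of the averaged curve is reported ×100.  With
    ``peak_of_mean=False`` the mean of the per-slice minima is used instead
    (the two coincide for synchronous contraction, and the default can only
    be the larger, i.e. less negative, of the two).
    """
    eps = _stack_eps(curves)
    if eps.shape[0] != alloc.total:
        raise InvalidMeasurementError(
            f"{eps.shape[0]} curves supplied but allocation covers {alloc.total} slices"
        )
    out: dict[str, float] = {}
    for region, rng in alloc.slice_ranges().items():
        block = eps[rng.start : rng.stop]
        if peak_of_mean:
            value = float(np.min(block.mean(axis=0)))
        else:
            value = float(np.mean(block.min(axis=1)))
        out[region] = 100.0 * value
    return RegionalStrains(acs=out["apex"], mcs=out["mid"], bcs=out["base"])


def global_strain(curves: list[StrainCurve], *, peak_of_mean: bool = True) -> float:
    """Peak GCS (%) — minimum of the all-slice mean strain curve, ×100."""
    eps = _stack_eps(curves)
    if peak_of_mean:
        return float(100.0 * np.min(eps.mean(axis=0)))
    return float(100.0 * np.mean(eps.min(axis=1)))
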