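"""Closed planar contour primitives.

An endocardial border on one short-axis cine frame is represented as a
:class:`Contour`: an ordered ring of 2-D points in millimetres.  The ring is
stored *open* — the first point is not repeated at the end; closure is
implicit — so the seam segment is never double-counted.  Perimeter (the
circumference entering the strain metric) and enclosed area (the blood-pool
cross-section entering slice-summation volumes) are the only measurements
the downstream pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contour",
    "InvalidContourError",
    "polygon_perimeter",
    "polygon_area",
    "make_circle_contour",
]


class InvalidContourError(ValueError):
    """Raised when a point ring cannot represent a closed contour."""


@dataclass(frozen=True)
class Contour:
    """A closed 2-D polygonal contour in millimetre coordinates.

    Parameters
    ----------
    points
        Array of shape ``(n, 2)`` with ``n >= 3``; the last point connects
        implicitly back to the first.
    """

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidContourError(f"expected (n, 2) point array, got shape {pts.shape}")
        if pts.shape[0] < 3:
            raise InvalidContourError(f"a contour needs >= 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError("contour coordinates must be finite")
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise InvalidContourError("consecutive duplicate points in contour")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _as_contour(contour: Contour | np.ndarray) -> Contour:
    return contour if isinstance(contour, Contour) else Contour(np.asarray(contour))


def polygon_perimeter(contour: Contour | np.ndarray) -> float:
    """Perimeter of the closed polygon, in mm.

    Sum of Euclidean edge lengths around the ring including the implicit
    closing edge.  Invariant under rigid motions and cyclic reordering;
    scales linearly under uniform scaling.
    """
    pts = _as_contour(contour).points
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Enclosed area of a simple closed polygon, in mm² (shoelace, absolute).

    Orientation-independent: clockwise and counter-clockwise rings give the
    same value.  Self-intersecting input is not detected.
    """
    pts = _as_contour(contour).points
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def make_circle_contour(
    radius: float,
    n_points: int = 100,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
) -> Contour:
    """Regular ``n_points``-gon inscribed in a circle of ``radius`` mm.

    The first vertex sits at polar angle ``phase`` (default 0).  As
    ``n_points`` grows, perimeter → 2πr and area → πr², monotonically from
    below.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if n_points < 3:
        raise InvalidContourError(f"n_points must be >= 3, got {n_points}")
    theta = phase + 2.0 * np.pi * np.arange(n_points) / n_points
    pts = np.column_stack([center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)])
    return Contour(pts)


def regular_polygon_area_factor(n_points: int) -> float:
    """Ratio of a regular n-gon's area to its circumscribing circle's πr².

    Equals ``n sin(2π/n) / (2π)``; used to size phantom radii so polygonal
    slice areas hit a target volume exactly.
    """
    if n_points < 3:
        raise InvalidContourError(f"n_points must be >= 3, got {n_points}")
    return float(n_points * np.sin(2.0 * np.pi / n_points) / (2.0 * np.pi))
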