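"""Planar geometry for fascicle architecture measurements.

Coordinate convention: continuous millimetre image coordinates with the
origin at the centre of the top-left pixel, x increasing rightward along
the transducer face and y increasing with tissue depth.  All public
quantities are expressed in mm and degrees; raw pixel coordinates never
leave the tracking internals.

The three tracked structures (superficial aponeurosis, deep aponeurosis,
candidate fascicle) are modelled as straight lines.  Fascicle length is
the distance between the fascicle line's intersections with the two
aponeurosis lines; pennation angle is the acute angle between the
fascicle and the deep aponeurosis.  Intersections are computed on the
infinite lines, so attachment points outside the imaged field of view
are obtained by extrapolation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSpec",
    "Segment2D",
    "Line2D",
    "StructureRole",
    "DegenerateGeometryError",
    "NoIntersectionError",
    "fit_line",
    "intersect",
    "fascicle_length",
    "pennation_angle",
]

#: |sin(angle)| below which two directions are treated as parallel.
PARALLEL_TOL = 1e-9


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    """z-component of the cross product of two 2-D vectors."""
    return float(a[0] * b[1] - a[1] * b[0])


class DegenerateGeometryError(ValueError):
    """Raised when points or segments do not define a usable line."""


class NoIntersectionError(ValueError):
    """Raised when two lines are parallel (or nearly so) and cannot intersect."""


class StructureRole(enum.Enum):
    """The three structures identified in the first frame of a video."""

    SUPERFICIAL_APONEUROSIS = "superficial_aponeurosis"
    DEEP_APONEUROSIS = "deep_aponeurosis"
    FASCICLE = "fascicle"


@dataclass(frozen=True)
class FrameSpec:
    """Acquisition geometry of one video: raster size, pixel pitch, frame rate.

    Parameters
    ----------
    width_px, height_px : int
        Raster dimensions in pixels.
    mm_per_px : float
        Isotropic pixel pitch in millimetres.
    frame_rate_hz : float
        Acquisition rate in frames per second.
    """

    width_px: int
    height_px: int
    mm_per_px: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def width_mm(self) -> float:
        """Physical field-of-view width (mm)."""
        return self.width_px * self.mm_per_px

    @property
    def height_mm(self) -> float:
        """Physical field-of-view depth (mm)."""
        return self.height_px * self.mm_per_px

    def contains_mm(self, points: np.ndarray) -> np.ndarray:
        """Elementwise test whether mm-coordinate points fall inside the raster.

        The raster spans pixel centres 0 .. (n-1)*mm_per_px in each axis.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x_ok = (p[:, 0] >= 0.0) & (p[:, 0] <= (self.width_px - 1) * self.mm_per_px)
        y_ok = (p[:, 1] >= 0.0) & (p[:, 1] <= (self.height_px - 1) * self.mm_per_px)
        return x_ok & y_ok


@dataclass(frozen=True)
class Segment2D:
    """A user-drawn line segment in mm image coordinates."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise DegenerateGeometryError("segment endpoints must be finite")
        if np.allclose(a, b):
            raise DegenerateGeometryError("segment endpoints coincide")

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([self.p0, self.p1], dtype=float)

    @property
    def midpoint(self) -> np.ndarray:
        return self.endpoints.mean(axis=0)

    @property
    def length(self) -> float:
        a, b = self.endpoints
        return float(np.linalg.norm(b - a))

    @property
    def direction(self) -> np.ndarray:
        a, b = self.endpoints
        d = b - a
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class Line2D:
    """An infinite line: anchor point plus unit direction.

    The representation is orientation-free: a line and the same line with
    its direction reversed compare equal under :meth:`isclose`.
    """

    anchor: tuple[float, float]
    direction: tuple[float, float] = field(default=(1.0, 0.0))

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise DegenerateGeometryError("line direction must be a nonzero vector")
        object.__setattr__(self, "direction", tuple(d / n))
        object.__setattr__(self, "anchor", tuple(float(v) for v in self.anchor))

    @property
    def anchor_arr(self) -> np.ndarray:
        return np.asarray(self.anchor, dtype=float)

    @property
    def direction_arr(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal (direction rotated +90 degrees)."""
        dx, dy = self.direction
        return np.array([-dy, dx])

    def distance_to(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance from points (mm) to the line."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.abs((p - self.anchor_arr) @ self.normal)

    def point_at(self, s: float) -> np.ndarray:
        """Point anchor + s * direction."""
        return self.anchor_arr + s * self.direction_arr

    def isclose(self, other: "Line2D", atol: float = 1e-9) -> bool:
        """Orientation-free equality: same line within ``atol``."""
        cross = abs(_cross2(self.direction_arr, other.direction_arr))
        if cross > atol:
            return False
        return bool(np.all(self.distance_to(other.anchor_arr) <= atol))


def fit_line(points: np.ndarray, method: str = "orthogonal") -> Line2D:
    """Fit a straight line to 2-D points.

    Parameters
    ----------
    points : (N, 2) array_like
        At least two non-coincident points, mm coordinates.
    method : {"orthogonal", "ols_yx"}
        ``orthogonal`` (default) minimises the perpendicular residuals:
        anchor = centroid, direction = principal axis of the centred
        points.  ``ols_yx`` is ordinary y-on-x regression, provided for
        comparison with slope-based pipelines; it is biased for steep
        fascicles and falls back to the orthogonal fit when the points
        are (near-)vertical.

    Returns
    -------
    Line2D

    Raises
    ------
    DegenerateGeometryError
        If fewer than two points are given or all points coincide.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least two 2-D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0):
        raise DegenerateGeometryError("all points coincide; no line defined")
    if method == "orthogonal":
        # Principal axis of the scatter: right singular vector of the
        # centred coordinates with the largest singular value.
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    elif method == "ols_yx":
        sxx = float(np.sum(centered[:, 0] ** 2))
        if sxx < 1e-12 * float(np.sum(centered**2)):
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            direction = vt[0]
        else:
            slope = float(np.sum(centered[:, 0] * centered[:, 1])) / sxx
            direction = np.array([1.0, slope])
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return Line2D(anchor=tuple(centroid), direction=tuple(direction))


def intersect(
    a: Line2D,
    b: Line2D,
    names: tuple[str, str] = ("line a", "line b"),
) -> np.ndarray:
    """Intersection point of two infinite lines (mm).

    The lines are extrapolated as needed, so the result may lie outside
    the imaged field of view.

    Raises
    ------
    NoIntersectionError
        If |sin(angle between the lines)| <= 1e-9, naming both lines.
    """
    cross = _cross2(a.direction_arr, b.direction_arr)
    if abs(cross) <= PARALLEL_TOL:
        raise NoIntersectionError(
            f"{names[0]} and {names[1]} are parallel (|sin angle| <= {PARALLEL_TOL:g}); "
            "no intersection"
        )
    delta = b.anchor_arr - a.anchor_arr
    s = _cross2(delta, b.direction_arr) / cross
    return a.point_at(s)


def fascicle_length(fascicle: Line2D, superficial: Line2D, deep: Line2D) -> float:
    """Fascicle length (mm): distance between the fascicle line's
    intersections with the superficial and deep aponeurosis lines."""
    p_sup = intersect(fascicle, superficial, names=("fascicle", "superficial aponeurosis"))
    p_deep = intersect(fascicle, deep, names=("fascicle", "deep aponeurosis"))
    return float(np.linalg.norm(p_sup - p_deep))


def pennation_angle(fascicle: Line2D, deep: Line2D) -> float:
    """Pennation angle (degrees): acute angle in (0, 90] between the
    fascicle and the deep aponeurosis.

    Independent of the sign of either line's direction vector.

    Raises
    ------
    DegenerateGeometryError
        If the fascicle is parallel to the deep aponeurosis (angle 0): a
        fascicle parallel to its aponeurosis has no attachment point.
    """
    cosang = abs(float(np.dot(fascicle.direction_arr, deep.direction_arr)))
    sinang = abs(_cross2(fascicle.direction_arr, deep.direction_arr))
    if sinang <= PARALLEL_TOL:
        raise DegenerateGeometryError(
            "fascicle is parallel to the deep aponeurosis; pennation undefined"
        )
    return float(np.degrees(np.arctan2(sinang, cosang)))
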