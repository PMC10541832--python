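"""Exact 2D primitives for radiograph-plane constructions.

Coordinate convention (radiograph display frame): x increases toward the
image right, y increases downward, units are millimetres once calibrated.
"Parallel to the ground" therefore means constant y.  Angles cross the API
in degrees; a *signed* angle is measured by the mathematical orientation of
this frame (``atan2(cross, dot)``), which appears clockwise on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError, NoIntersectionError

#: tolerance on normalized cross products for parallelism / collinearity
PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class Point2:
    """A point in the calibrated radiograph plane, in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def from_array(a) -> "Point2":
        return Point2(float(a[0]), float(a[1]))

    def mirrored(self) -> "Point2":
        """Reflection about the vertical axis x = 0."""
        return Point2(-self.x, self.y)

    def scaled(self, k: float) -> "Point2":
        return Point2(k * self.x, k * self.y)


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale, derived from a 100 x 100 mm reference
    square on the radiograph.  ``is_calibrated`` is False when the scale is
    a nominal assumption rather than a measured square."""

    mm_per_pixel: float = 1.0
    is_calibrated: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_pixel) and self.mm_per_pixel > 0):
            from .errors import CalibrationError

            raise CalibrationError(
                f"mm_per_pixel must be positive, got {self.mm_per_pixel}"
            )


def _unit(vx: float, vy: float) -> tuple[float, float]:
    n = math.hypot(vx, vy)
    if n < 1e-15:
        raise InvalidGeometryError("zero-length direction")
    return vx / n, vy / n


@dataclass(frozen=True)
class Line2:
    """An infinite oriented line: origin point plus unit direction."""

    origin: Point2
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if abs(math.hypot(self.dx, self.dy) - 1.0) > 1e-12:
            raise InvalidGeometryError("Line2 direction must be unit length")

    # -- constructors -------------------------------------------------
    @staticmethod
    def from_direction(origin: Point2, dx: float, dy: float) -> "Line2":
        ux, uy = _unit(dx, dy)
        return Line2(origin, ux, uy)

    @staticmethod
    def through(p: Point2, q: Point2) -> "Line2":
        """Oriented line from p toward q."""
        return Line2.from_direction(p, q.x - p.x, q.y - p.y)

    # -- queries ------------------------------------------------------
    @property
    def direction(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)

    def point_at(self, t: float) -> Point2:
        return Point2(self.origin.x + t * self.dx, self.origin.y + t * self.dy)

    def param_of_y(self, y: float) -> float:
        """Parameter t with point_at(t).y == y; requires a non-horizontal line."""
        if abs(self.dy) < PARALLEL_TOL:
            raise InvalidGeometryError("line is horizontal; no unique crossing of y")
        return (y - self.origin.y) / self.dy

    def mirrored(self) -> "Line2":
        return Line2(self.origin.mirrored(), -self.dx, self.dy)

    def scaled(self, k: float) -> "Line2":
        return Line2(self.origin.scaled(k), self.dx, self.dy)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def distance(p: Point2, q: Point2) -> float:
    return math.hypot(p.x - q.x, p.y - q.y)


def signed_angle_deg(ux: float, uy: float, vx: float, vy: float) -> float:
    """Signed angle from direction u to direction v, in (-180, 180] degrees,
    positive in the mathematical orientation of the (x right, y down) frame."""
    cross = ux * vy - uy * vx
    dot = ux * vx + uy * vy
    if abs(cross) < 1e-300 and abs(dot) < 1e-300:
        raise InvalidGeometryError("zero-length direction in angle")
    ang = math.degrees(math.atan2(cross, dot))
    if ang <= -180.0:
        ang += 360.0
    return ang


def angle_between(l1: Line2, l2: Line2, convention: str = "acute") -> float:
    """Angle between two lines in degrees.

    ``acute``  — unsigned line-to-line angle in [0, 90].
    ``signed`` — direction-to-direction angle in (-180, 180], measured from
    l1's direction to l2's direction in the frame's mathematical orientation.
    """
    s = signed_angle_deg(l1.dx, l1.dy, l2.dx, l2.dy)
    if convention == "signed":
        return s
    if convention == "acute":
        a = abs(s)
        return 180.0 - a if a > 90.0 else a
    raise ValueError(f"unknown angle convention {convention!r}")


def angle_between_directions(u, v) -> float:
    """Unsigned angle in [0, 180] degrees between two direction vectors."""
    ux, uy = _unit(float(u[0]), float(u[1]))
    vx, vy = _unit(float(v[0]), float(v[1]))
    return abs(signed_angle_deg(ux, uy, vx, vy))


def rotate_about(p: Point2, center: Point2, theta_deg: float) -> Point2:
    """Rotate p about center by theta degrees (mathematical orientation)."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    rx, ry = p.x - center.x, p.y - center.y
    return Point2(center.x + c * rx - s * ry, center.y + s * rx + c * ry)


def rotate_direction(dx: float, dy: float, theta_deg: float) -> tuple[float, float]:
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return c * dx - s * dy, s * dx + c * dy


def rotate_line_about(line: Line2, center: Point2, theta_deg: float) -> Line2:
    origin = rotate_about(line.origin, center, theta_deg)
    dx, dy = rotate_direction(line.dx, line.dy, theta_deg)
    return Line2.from_direction(origin, dx, dy)


def intersect(l1: Line2, l2: Line2) -> Point2:
    """Intersection point of two non-parallel lines.

    Solves ``o1 + t d1 = o2 + s d2`` for t; raises :class:`NoIntersectionError`
    when the normalized cross product of the directions is below tolerance.
    """
    denom = l1.dx * l2.dy - l1.dy * l2.dx
    if abs(denom) < PARALLEL_TOL:
        raise NoIntersectionError("lines are parallel within tolerance")
    ox = l2.origin.x - l1.origin.x
    oy = l2.origin.y - l1.origin.y
    t = (ox * l2.dy - oy * l2.dx) / denom
    return l1.point_at(t)


def horizontal_through(p: Point2) -> Line2:
    """The line parallel to the ground (constant y) through p."""
    return Line2(p, 1.0, 0.0)


def project_param(line: Line2, p: Point2) -> float:
    """Parameter of the orthogonal projection of p onto line."""
    return (p.x - line.origin.x) * line.dx + (p.y - line.origin.y) * line.dy
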