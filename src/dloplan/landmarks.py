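"""Calibrated landmark container for one lower limb.

All downstream analysis runs in a canonical right-limb frame in which the
tibial *medial* side is toward -x and y increases distally (down the image).
A left limb is handled by mirroring about a vertical axis on the way into
every operation (one code path; mirror symmetry is a tested invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .errors import InvalidGeometryError
from .geometry import Calibration, Point2, distance

Segment = tuple[Point2, Point2]


def _mirror_segment(seg: Segment) -> Segment:
    return (seg[0].mirrored(), seg[1].mirrored())


def _scale_segment(seg: Segment, k: float) -> Segment:
    return (seg[0].scaled(k), seg[1].scaled(k))


@dataclass(frozen=True)
class LimbLandmarks:
    """Calibrated 2D anatomical points and cortical segments for one limb.

    Points are in millimetres.  ``plateau_medial`` / ``plateau_lateral`` are
    the tangent endpoints of the tibial plateau (osteophytes excluded);
    ``condyle_medial`` / ``condyle_lateral`` the distal femoral condylar
    tangent endpoints.  Cortical segments are straight local models of the
    bone cortex near the osteotomy levels.  Explicit hinge points, when
    present, override the offset-based hinge derivation.
    """

    side: str  # "left" | "right"
    hip_center: Point2
    plateau_medial: Point2
    plateau_lateral: Point2
    condyle_medial: Point2
    condyle_lateral: Point2
    ankle_center: Point2
    femoral_medial_cortex: Segment
    femoral_lateral_cortex: Segment
    tibial_medial_cortex: Segment
    tibial_lateral_cortex: Segment
    calibration: Calibration = Calibration()
    femoral_hinge: Optional[Point2] = None
    tibial_hinge: Optional[Point2] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidGeometryError(f"side must be left|right, got {self.side!r}")
        if self.plateau_width <= 0:
            raise InvalidGeometryError("tibial plateau width must be positive")
        plateau_y = 0.5 * (self.plateau_medial.y + self.plateau_lateral.y)
        if not self.hip_center.y < plateau_y:
            raise InvalidGeometryError("hip center must be superior to the plateau tangent")
        if not self.ankle_center.y > plateau_y:
            raise InvalidGeometryError("ankle center must be inferior to the plateau tangent")
        for name in (
            "femoral_medial_cortex",
            "femoral_lateral_cortex",
            "tibial_medial_cortex",
            "tibial_lateral_cortex",
        ):
            a, b = getattr(self, name)
            if distance(a, b) <= 0:
                raise InvalidGeometryError(f"degenerate cortical segment {name}")

    # ------------------------------------------------------------------
    @property
    def plateau_width(self) -> float:
        return distance(self.plateau_medial, self.plateau_lateral)

    @property
    def knee_center(self) -> Point2:
        """Midpoint of the plateau tangent; shared knee center of both
        mechanical axes (keeps HKA, MPTA and LDFA mutually consistent)."""
        return Point2(
            0.5 * (self.plateau_medial.x + self.plateau_lateral.x),
            0.5 * (self.plateau_medial.y + self.plateau_lateral.y),
        )

    # ------------------------------------------------------------------
    def mirror(self) -> "LimbLandmarks":
        """Reflect about the vertical axis and toggle the side flag."""
        return replace(
            self,
            side="left" if self.side == "right" else "right",
            hip_center=self.hip_center.mirrored(),
            plateau_medial=self.plateau_medial.mirrored(),
            plateau_lateral=self.plateau_lateral.mirrored(),
            condyle_medial=self.condyle_medial.mirrored(),
            condyle_lateral=self.condyle_lateral.mirrored(),
            ankle_center=self.ankle_center.mirrored(),
            femoral_medial_cortex=_mirror_segment(self.femoral_medial_cortex),
            femoral_lateral_cortex=_mirror_segment(self.femoral_lateral_cortex),
            tibial_medial_cortex=_mirror_segment(self.tibial_medial_cortex),
            tibial_lateral_cortex=_mirror_segment(self.tibial_lateral_cortex),
            femoral_hinge=self.femoral_hinge.mirrored() if self.femoral_hinge else None,
            tibial_hinge=self.tibial_hinge.mirrored() if self.tibial_hinge else None,
        )

    def canonical(self) -> "LimbLandmarks":
        """Return the right-limb-frame view (mirror iff the limb is left)."""
        return self.mirror() if self.side == "left" else self

    def scaled(self, k: float) -> "LimbLandmarks":
        """Uniformly scale all coordinates by k (for equivariance checks)."""
        if k <= 0:
            raise InvalidGeometryError("scale factor must be positive")
        return replace(
            self,
            hip_center=self.hip_center.scaled(k),
            plateau_medial=self.plateau_medial.scaled(k),
            plateau_lateral=self.plateau_lateral.scaled(k),
            condyle_medial=self.condyle_medial.scaled(k),
            condyle_lateral=self.condyle_lateral.scaled(k),
            ankle_center=self.ankle_center.scaled(k),
            femoral_medial_cortex=_scale_segment(self.femoral_medial_cortex, k),
            femoral_lateral_cortex=_scale_segment(self.femoral_lateral_cortex, k),
            tibial_medial_cortex=_scale_segment(self.tibial_medial_cortex, k),
            tibial_lateral_cortex=_scale_segment(self.tibial_lateral_cortex, k),
            femoral_hinge=self.femoral_hinge.scaled(k) if self.femoral_hinge else None,
            tibial_hinge=self.tibial_hinge.scaled(k) if self.tibial_hinge else None,
        )
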