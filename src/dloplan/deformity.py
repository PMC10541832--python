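"""Paley-style frontal-plane deformity analysis.

Computes the mechanical angles of the lower limb from a landmark set:

* **HKA deviation** — angle between the femoral (hip→knee) and tibial
  (knee→ankle) mechanical axes, reported as deviation from a straight
  180° limb, varus positive.
* **MPTA** — medial angle between the tibial plateau tangent and the
  knee→ankle mechanical axis.
* **LDFA** — lateral angle between the distal femoral condylar tangent and
  the hip→knee mechanical axis.
* **JLCA** — angle between the condylar and plateau tangents, positive when
  they converge medially (varus wear pattern).
* **Mikulicz line** — the weight-bearing line from hip center to ankle
  center, its crossing of the plateau tangent expressed as a percentage of
  plateau width from the medial edge (WBL %), and two joint-line-obliquity
  indices: the medial-inferior angle of the Mikulicz line against the
  plateau tangent, and against the bisector of the JLCA (the M-JL angle).

The knee center of both mechanical axes is the midpoint of the plateau
tangent, so the small-angle identity
``HKA ≈ (90 − MPTA) + (LDFA − 90) + JLCA`` holds for varus limbs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidGeometryError
from .geometry import (
    Line2,
    Point2,
    horizontal_through,
    intersect,
    signed_angle_deg,
    _unit,
)
from .landmarks import LimbLandmarks


@dataclass(frozen=True)
class DeformityAnalysis:
    """Scalar deformity parameters plus the Mikulicz line (canonical frame)."""

    hka_deviation: float  # degrees, varus positive
    mpta: float  # degrees
    ldfa: float  # degrees
    jlca: float  # degrees, medial convergence positive
    mikulicz_line: Line2
    wbl_percent: float  # % of plateau width from the medial edge
    mjl_angle: float  # degrees, Mikulicz vs bisector of JLCA
    jlo_plateau_angle: float  # degrees, Mikulicz vs plateau tangent

    @property
    def hka_full_angle(self) -> float:
        """HKA in the full-angle form (180° = straight limb; <180 varus)."""
        return 180.0 - self.hka_deviation


def _acute_range_check(name: str, value: float) -> None:
    if not 45.0 < value < 135.0:
        raise InvalidGeometryError(f"{name} = {value:.2f} degrees outside (45, 135)")


def analyze(landmarks: LimbLandmarks) -> DeformityAnalysis:
    """Full mechanical angle analysis of one limb.

    Raises
    ------
    InvalidGeometryError
        If the Mikulicz line is parallel to the plateau tangent or an angle
        falls outside its anatomical range.
    """
    lm = landmarks.canonical()
    knee = lm.knee_center

    med_plat = _unit(lm.plateau_medial.x - lm.plateau_lateral.x,
                     lm.plateau_medial.y - lm.plateau_lateral.y)
    lat_plat = (-med_plat[0], -med_plat[1])
    lat_cond = _unit(lm.condyle_lateral.x - lm.condyle_medial.x,
                     lm.condyle_lateral.y - lm.condyle_medial.y)

    tib_axis = _unit(lm.ankle_center.x - knee.x, lm.ankle_center.y - knee.y)
    fem_axis_up = _unit(lm.hip_center.x - knee.x, lm.hip_center.y - knee.y)
    fem_axis_down = (-fem_axis_up[0], -fem_axis_up[1])

    mpta = math.degrees(math.acos(max(-1.0, min(1.0,
        med_plat[0] * tib_axis[0] + med_plat[1] * tib_axis[1]))))
    ldfa = math.degrees(math.acos(max(-1.0, min(1.0,
        lat_cond[0] * fem_axis_up[0] + lat_cond[1] * fem_axis_up[1]))))
    _acute_range_check("MPTA", mpta)
    _acute_range_check("LDFA", ldfa)

    jlca = signed_angle_deg(*lat_cond, *lat_plat)
    hka_deviation = signed_angle_deg(*fem_axis_down, *tib_axis)

    mikulicz = Line2.through(lm.hip_center, lm.ankle_center)
    plateau_line = Line2.through(lm.plateau_medial, lm.plateau_lateral)
    crossing = intersect(mikulicz, plateau_line)
    along = ((crossing.x - lm.plateau_medial.x) * lat_plat[0]
             + (crossing.y - lm.plateau_medial.y) * lat_plat[1])
    wbl_percent = 100.0 * along / lm.plateau_width

    # medial-inferior angles: medial reference direction vs distally-pointing
    # Mikulicz direction
    mik_down = (mikulicz.dx, mikulicz.dy)
    if mik_down[1] < 0:
        mik_down = (-mik_down[0], -mik_down[1])
    jlo_plateau = math.degrees(math.acos(max(-1.0, min(1.0,
        med_plat[0] * mik_down[0] + med_plat[1] * mik_down[1]))))

    med_bis = _unit(-(lat_plat[0] + lat_cond[0]), -(lat_plat[1] + lat_cond[1]))
    mjl = math.degrees(math.acos(max(-1.0, min(1.0,
        med_bis[0] * mik_down[0] + med_bis[1] * mik_down[1]))))

    return DeformityAnalysis(
        hka_deviation=hka_deviation,
        mpta=mpta,
        ldfa=ldfa,
        jlca=jlca,
        mikulicz_line=mikulicz,
        wbl_percent=wbl_percent,
        mjl_angle=mjl,
        jlo_plateau_angle=jlo_plateau,
    )


def mjl_angle(landmarks: LimbLandmarks) -> float:
    """Medial-inferior angle between the Mikulicz line and the bisector of
    the JLCA (femoral condylar vs tibial plateau tangents).  Degenerates to
    the plateau joint-line-obliquity angle when JLCA = 0."""
    return analyze(landmarks).mjl_angle


def correction_point(landmarks: LimbLandmarks, target_percent: float) -> Point2:
    """Point on the plateau tangent at ``target_percent`` of plateau width
    from the medial edge (canonical frame)."""
    lm = landmarks.canonical()
    f = target_percent / 100.0
    return Point2(
        lm.plateau_medial.x + f * (lm.plateau_lateral.x - lm.plateau_medial.x),
        lm.plateau_medial.y + f * (lm.plateau_lateral.y - lm.plateau_medial.y),
    )
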