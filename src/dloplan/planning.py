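"""Geometric double-level osteotomy planning driven by the predicted
post-operative joint-line obliquity.

The construction works backwards from the desired post-operative state:

1. Choose the correction point on the tibial plateau tangent (default
   62.5 % of plateau width from the medial edge, a Fujisawa-type slight
   overcorrection target).
2. Draw the *new loading axis* through the correction point, subtending a
   fixed medial-inferior angle with the plateau tangent (default 88°, a
   slightly varus post-operative joint-line obliquity).  The plateau
   tangent — the fixed fragment — is the reference: the axis is not forced
   vertical, its angle to the joint line is what is prescribed.
3. Place the osteotomy hinge points: tibial hinge on the lateral tibial
   cortex ~15 mm below the lateral joint line (near the fibular head);
   femoral hinge on the medial femoral cortex ~40 mm proximal to the
   medial condylar tangent (adductor-tubercle region).
4. Femoral correction angle = angle at the femoral hinge between the
   A-line (hinge → hip center) and the B-line (hinge → intersection of the
   new axis with the horizontal through the hip center).  Tibial correction
   angle = angle at the tibial hinge between the C-line (hinge → ankle
   center) and the D-line (hinge → intersection of the new axis with the
   horizontal through the ankle center).
5. Draw the oblique osteotomy lines through the hinges, swing each by its
   correction angle about its hinge, and read the millimetric wedge gap as
   the distance between the two intersections with the far cortex
   (lateral femoral closing gap, medial tibial opening gap).

An intra-articular (soft-tissue) share of the deformity, flagged by
JLCA > 2°, can be deducted with the (JLCA − 2)/2 rule; because the plateau
tangent is the method's joint-line reference, that share is attributed to —
and subtracted entirely from — the femoral correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .deformity import DeformityAnalysis, analyze, correction_point
from .errors import (
    CalibrationError,
    InvalidGeometryError,
    OutOfRangeError,
    UnsupportedDeformityError,
)
from .geometry import (
    Calibration,
    Line2,
    Point2,
    distance,
    horizontal_through,
    intersect,
    project_param,
    rotate_direction,
    rotate_line_about,
    signed_angle_deg,
)
from .landmarks import LimbLandmarks, Segment

_ZERO_ANGLE = 1e-9  # degrees; below this a rotation is treated as identity
_TARGET_EPS = 1e-6  # % of plateau width; equality band at the target


@dataclass(frozen=True)
class PlanParameters:
    """Tunable planning parameters (defaults are the validated protocol)."""

    target_percent: float = 62.5  # % of plateau width from the medial cortex
    nmjl_angle: float = 88.0  # degrees, medial-inferior angle of the new axis
    tibial_hinge_offset: float = 15.0  # mm distal to the lateral joint line
    femoral_hinge_offset: float = 40.0  # mm proximal to the medial condylar tangent
    tibial_osteotomy_entry_offset: float = 40.0  # mm distal to joint line, medial cortex
    osteotomy_obliquity: float = 20.0  # degrees vs the bone's perpendicular axis
    uncalibrated_gap_increment: float = 0.03  # fractional gap increment
    apply_jlca_adjustment: bool = True  # deduct (JLCA-2)/2 when JLCA > 2

    def __post_init__(self) -> None:
        if not 0.0 < self.target_percent < 100.0:
            raise ValueError("target_percent must be in (0, 100)")
        if not 80.0 <= self.nmjl_angle <= 100.0:
            raise ValueError("nmjl_angle must be in [80, 100] degrees")
        for name in ("tibial_hinge_offset", "femoral_hinge_offset",
                     "tibial_osteotomy_entry_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PlanConstruction:
    """Full construction geometry (canonical right-limb frame)."""

    correction_point: Point2
    new_axis: Line2
    femoral_hinge: Point2
    tibial_hinge: Point2
    line_A: Line2
    line_B: Line2
    line_C: Line2
    line_D: Line2
    femoral_osteotomy: Line2
    tibial_osteotomy: Line2
    rotated_femoral_osteotomy: Line2
    rotated_tibial_osteotomy: Line2
    #: mathematically signed fragment rotations in the canonical frame
    femoral_rotation_signed: float = 0.0
    tibial_rotation_signed: float = 0.0


@dataclass(frozen=True)
class PlanResult:
    """Correction angles (degrees) and wedge gaps (mm) for one limb."""

    femoral_correction: float  # lateral closing wedge, degrees
    tibial_correction: float  # medial opening wedge, degrees
    femoral_gap: float  # mm at the lateral femoral cortex
    tibial_gap: float  # mm at the medial tibial cortex
    jlca_adjustment: float  # degrees deducted from the femoral correction
    construction: PlanConstruction
    calibrated: bool
    analysis: DeformityAnalysis = field(repr=False, default=None)

    @property
    def total_correction(self) -> float:
        return self.femoral_correction + self.tibial_correction


@dataclass(frozen=True)
class EligibilityResult:
    """Inclusion/exclusion verdicts for double-level osteotomy."""

    ldfa_criterion: bool  # LDFA > 90
    mpta_criterion: bool  # MPTA < 85
    hto_overcorrection_criterion: bool  # post single-HTO MPTA > 94
    magnitude_criterion: bool  # total correction > 10 deg or any gap > 15 mm
    jlca_exclusion: bool  # JLCA > 6
    dlo_indicated: bool


# ---------------------------------------------------------------------------
# elementary rules
# ---------------------------------------------------------------------------

def jlca_soft_tissue_adjustment(jlca: float) -> float:
    """Soft-tissue share of the deformity: max(0, (JLCA - 2) / 2) degrees."""
    if jlca < 0:
        raise ValueError("jlca must be non-negative")
    return max(0.0, (jlca - 2.0) / 2.0)


def apply_uncalibrated_increment(gap: float, calibration: Calibration,
                                 increment: float = 0.03) -> float:
    """Inflate a gap by the customary 3 % when no calibration square was
    available; calibrated gaps pass through unchanged."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if calibration.is_calibrated:
        return gap
    return gap * (1.0 + increment)


# ---------------------------------------------------------------------------
# hinge derivation
# ---------------------------------------------------------------------------

def _point_on_segment_at_y(seg: Segment, y: float, name: str) -> Point2:
    line = Line2.through(seg[0], seg[1])
    t = line.param_of_y(y)
    t0, t1 = 0.0, distance(seg[0], seg[1])
    lo, hi = min(t0, t1), max(t0, t1)
    if not lo - 1e-9 <= t <= hi + 1e-9:
        raise OutOfRangeError(
            f"requested level y={y:.1f} mm falls outside the {name} segment")
    return line.point_at(t)


def derive_hinges(landmarks: LimbLandmarks,
                  params: PlanParameters = PlanParameters()) -> tuple[Point2, Point2]:
    """Place the femoral and tibial hinge points.

    Explicit hinge landmarks, when supplied, are passed through unchanged.
    Otherwise the tibial hinge sits on the lateral tibial cortex at the
    configured vertical drop below the lateral plateau edge, and the femoral
    hinge on the medial femoral cortex at the configured vertical rise above
    the medial condylar tangent point.
    """
    lm = landmarks.canonical()
    if lm.femoral_hinge is not None and lm.tibial_hinge is not None:
        return lm.femoral_hinge, lm.tibial_hinge

    tibial = lm.tibial_hinge or _point_on_segment_at_y(
        lm.tibial_lateral_cortex,
        lm.plateau_lateral.y + params.tibial_hinge_offset,
        "lateral tibial cortex",
    )
    femoral = lm.femoral_hinge or _point_on_segment_at_y(
        lm.femoral_medial_cortex,
        lm.condyle_medial.y - params.femoral_hinge_offset,
        "medial femoral cortex",
    )
    return femoral, tibial


# ---------------------------------------------------------------------------
# osteotomy lines and gaps
# ---------------------------------------------------------------------------

def _new_axis(lm: LimbLandmarks, params: PlanParameters) -> tuple[Point2, Line2]:
    cp = correction_point(lm, params.target_percent)
    med = (lm.plateau_medial.x - lm.plateau_lateral.x,
           lm.plateau_medial.y - lm.plateau_lateral.y)
    n = math.hypot(*med)
    med = (med[0] / n, med[1] / n)
    # rotate the medial plateau direction by -nmjl (math orientation) so the
    # axis descends distally while subtending the medial-inferior angle
    dx, dy = rotate_direction(med[0], med[1], -params.nmjl_angle)
    return cp, Line2.from_direction(cp, dx, dy)


def _femoral_osteotomy_line(lm: LimbLandmarks, hinge: Point2,
                            params: PlanParameters) -> Line2:
    """Oblique femoral cut through the hinge: descending lateral → medial at
    ``osteotomy_obliquity`` to the perpendicular of the femoral mechanical
    axis."""
    knee = lm.knee_center
    ux, uy = (lm.hip_center.x - knee.x, lm.hip_center.y - knee.y)
    n = math.hypot(ux, uy)
    ux, uy = ux / n, uy / n  # proximal
    px, py = -uy, ux  # perpendicular, lateral-pointing for a canonical limb
    if px < 0:
        px, py = -px, -py
    dx, dy = rotate_direction(px, py, -params.osteotomy_obliquity)
    return Line2.from_direction(hinge, dx, dy)


def _tibial_osteotomy_line(lm: LimbLandmarks, hinge: Point2,
                           params: PlanParameters) -> tuple[Line2, Point2]:
    entry = _point_on_segment_at_y(
        lm.tibial_medial_cortex,
        lm.plateau_medial.y + params.tibial_osteotomy_entry_offset,
        "medial tibial cortex",
    )
    return Line2.through(entry, hinge), entry


def _wedge_gap(osteotomy: Line2, hinge: Point2, signed_deg: float,
               cortex: Segment) -> tuple[float, Line2]:
    """Distance between the intersections of the original and swung osteotomy
    lines with the straight cortex line."""
    if abs(signed_deg) < _ZERO_ANGLE:
        return 0.0, osteotomy
    rotated = rotate_line_about(osteotomy, hinge, signed_deg)
    cortex_line = Line2.through(cortex[0], cortex[1])
    g1 = intersect(osteotomy, cortex_line)
    g2 = intersect(rotated, cortex_line)
    return distance(g1, g2), rotated


# ---------------------------------------------------------------------------
# the planner
# ---------------------------------------------------------------------------

def plan_nmjl(landmarks: LimbLandmarks,
              params: PlanParameters = PlanParameters()) -> PlanResult:
    """Run the full double-level planning construction for a varus limb.

    Raises
    ------
    UnsupportedDeformityError
        If the weight-bearing line already crosses lateral to the target
        (valgus relative to the plan); the method is validated for varus
        correction only.
    """
    lm = landmarks.canonical()
    stats = analyze(lm)
    if stats.wbl_percent > params.target_percent + _TARGET_EPS:
        raise UnsupportedDeformityError(
            f"weight-bearing line at {stats.wbl_percent:.1f}% is already "
            f"lateral to the {params.target_percent}% target")

    cp, new_axis = _new_axis(lm, params)
    femoral_hinge, tibial_hinge = derive_hinges(lm, params)

    line_a = Line2.through(femoral_hinge, lm.hip_center)
    x_f = intersect(new_axis, horizontal_through(lm.hip_center))
    line_b = Line2.through(femoral_hinge, x_f)
    fem_signed = signed_angle_deg(line_a.dx, line_a.dy, line_b.dx, line_b.dy)

    line_c = Line2.through(tibial_hinge, lm.ankle_center)
    x_t = intersect(new_axis, horizontal_through(lm.ankle_center))
    line_d = Line2.through(tibial_hinge, x_t)
    tib_signed = signed_angle_deg(line_c.dx, line_c.dy, line_d.dx, line_d.dy)

    femoral_correction = abs(fem_signed)
    tibial_correction = abs(tib_signed)

    # soft-tissue deduction, attributed wholly to the femur
    jlca_adj = 0.0
    if params.apply_jlca_adjustment and stats.jlca > 2.0:
        requested = jlca_soft_tissue_adjustment(stats.jlca)
        jlca_adj = min(requested, femoral_correction)
        if requested > femoral_correction:
            warnings.warn(
                "JLCA adjustment exceeds the femoral correction; "
                "femoral angle floored at 0", stacklevel=2)
        new_fem = femoral_correction - jlca_adj
        fem_signed = math.copysign(new_fem, fem_signed) if new_fem > 0 else 0.0
        femoral_correction = new_fem

    fem_osteotomy = _femoral_osteotomy_line(lm, femoral_hinge, params)
    tib_osteotomy, _entry = _tibial_osteotomy_line(lm, tibial_hinge, params)

    femoral_gap, fem_rot_line = _wedge_gap(
        fem_osteotomy, femoral_hinge, fem_signed, lm.femoral_lateral_cortex)
    tibial_gap, tib_rot_line = _wedge_gap(
        tib_osteotomy, tibial_hinge, tib_signed, lm.tibial_medial_cortex)

    femoral_gap = apply_uncalibrated_increment(
        femoral_gap, lm.calibration, params.uncalibrated_gap_increment)
    tibial_gap = apply_uncalibrated_increment(
        tibial_gap, lm.calibration, params.uncalibrated_gap_increment)

    construction = PlanConstruction(
        correction_point=cp,
        new_axis=new_axis,
        femoral_hinge=femoral_hinge,
        tibial_hinge=tibial_hinge,
        line_A=line_a,
        line_B=line_b,
        line_C=line_c,
        line_D=line_d,
        femoral_osteotomy=fem_osteotomy,
        tibial_osteotomy=tib_osteotomy,
        rotated_femoral_osteotomy=fem_rot_line,
        rotated_tibial_osteotomy=tib_rot_line,
        femoral_rotation_signed=fem_signed,
        tibial_rotation_signed=tib_signed,
    )
    return PlanResult(
        femoral_correction=femoral_correction,
        tibial_correction=tibial_correction,
        femoral_gap=femoral_gap,
        tibial_gap=tibial_gap,
        jlca_adjustment=jlca_adj,
        construction=construction,
        calibrated=lm.calibration.is_calibrated,
        analysis=stats,
    )


def plan_single_hto(landmarks: LimbLandmarks,
                    params: PlanParameters = PlanParameters()
                    ) -> tuple[float, float]:
    """Miniaci-style single high tibial osteotomy check.

    The desired axis runs from the (unmoved) hip center through the
    correction point; the tibial-only correction is the hinge angle between
    the line to the ankle and the line to that axis's crossing of the
    horizontal through the ankle.  Returns
    ``(tibial_only_correction, postop_mpta)``.
    """
    lm = landmarks.canonical()
    stats = analyze(lm)
    if stats.wbl_percent > params.target_percent + _TARGET_EPS:
        raise UnsupportedDeformityError(
            "limb is already at or lateral to the target")
    cp = correction_point(lm, params.target_percent)
    _, tibial_hinge = derive_hinges(lm, params)
    line_c = Line2.through(tibial_hinge, lm.ankle_center)
    if abs(stats.wbl_percent - params.target_percent) <= _TARGET_EPS:
        return 0.0, stats.mpta
    desired = Line2.through(lm.hip_center, cp)
    x_t = intersect(desired, horizontal_through(lm.ankle_center))
    line_d = Line2.through(tibial_hinge, x_t)
    corr = abs(signed_angle_deg(line_c.dx, line_c.dy, line_d.dx, line_d.dy))
    return corr, stats.mpta + corr


def check_eligibility(analysis: DeformityAnalysis,
                      hto: tuple[float, float],
                      plan: PlanResult) -> EligibilityResult:
    """Apply the double-level osteotomy inclusion/exclusion thresholds
    (all strict inequalities): LDFA > 90 with MPTA < 85; a single-HTO plan
    overcorrecting MPTA beyond 94; or a large correction (> 10 degrees total
    or > 15 mm in any gap); excluded when JLCA > 6."""
    ldfa_c = analysis.ldfa > 90.0
    mpta_c = analysis.mpta < 85.0
    hto_c = hto[1] > 94.0
    magnitude_c = (plan.total_correction > 10.0
                   or plan.femoral_gap > 15.0
                   or plan.tibial_gap > 15.0)
    jlca_x = analysis.jlca > 6.0
    indicated = (ldfa_c and mpta_c and (hto_c or magnitude_c)) and not jlca_x
    return EligibilityResult(
        ldfa_criterion=ldfa_c,
        mpta_criterion=mpta_c,
        hto_overcorrection_criterion=hto_c,
        magnitude_criterion=magnitude_c,
        jlca_exclusion=jlca_x,
        dlo_indicated=indicated,
    )
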