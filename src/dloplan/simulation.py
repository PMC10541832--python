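"""Rigid-fragment virtual osteotomy simulation and exact two-target solver.

The knee block (distal femur + proximal tibia between the two osteotomies)
is the static reference, matching how the plateau tangent stays fixed in
planning drawings.  A femoral rotation swings the proximal femur (hip side)
about the femoral hinge; a tibial rotation swings the distal tibia (ankle
side) about the tibial hinge.  The interactive "progressively rotate until
the targets are met" procedure of segmentation software is replaced by a
damped Newton iteration on the 2x2 system

    wbl_percent(rotations)      = target_percent
    jlo_plateau_angle(rotations) = target_jlo

with a finite-difference Jacobian, giving a deterministic, machine-precision
oracle against which the geometric planner is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .deformity import analyze
from .errors import ConvergenceError, UnsupportedDeformityError
from .geometry import Point2, rotate_about
from .landmarks import LimbLandmarks
from .planning import (
    PlanConstruction,
    PlanParameters,
    PlanResult,
    _wedge_gap,
    derive_hinges,
)

#: wedge-positive → mathematically-signed rotation in the canonical frame:
#: a femoral lateral *closing* wedge swings the hip laterally (math +),
#: a tibial medial *opening* wedge swings the ankle laterally (math -).
_FEMORAL_MATH_SIGN = +1.0
_TIBIAL_MATH_SIGN = -1.0

#: convergence tolerances, an order of magnitude below reported human
#: measurement error (< 1 degree / < 2 mm)
PERCENT_TOL = 0.05
ANGLE_TOL = 0.01


@dataclass(frozen=True)
class FragmentRotation:
    """Fragment rotations in the wedge convention: femoral closing-wedge
    positive, tibial opening-wedge positive (degrees)."""

    femoral: float
    tibial: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.femoral) and np.isfinite(self.tibial)):
            raise ValueError("rotations must be finite")
        if max(abs(self.femoral), abs(self.tibial)) >= 45.0:
            raise ValueError("fragment rotations must be below 45 degrees")


@dataclass(frozen=True)
class VSSResult:
    """Solved rotations and the achieved post-operative alignment."""

    rotations: FragmentRotation
    postop_hip: Point2
    postop_ankle: Point2
    achieved_percent: float
    achieved_jlo_angle: float
    converged: bool
    iterations: int


def rotation_from_plan(plan: PlanResult) -> FragmentRotation:
    """Wedge-convention rotations equivalent to a geometric plan."""
    c = plan.construction
    return FragmentRotation(
        femoral=_FEMORAL_MATH_SIGN * c.femoral_rotation_signed,
        tibial=_TIBIAL_MATH_SIGN * c.tibial_rotation_signed,
    )


def apply_rotations(landmarks: LimbLandmarks,
                    rot: FragmentRotation,
                    hinges: tuple[Point2, Point2] | None = None) -> LimbLandmarks:
    """Rotate the hip about the femoral hinge and the ankle about the tibial
    hinge; the knee block (plateau and condylar tangents, hinge-adjacent
    bone) stays fixed.  Returns a new landmark set in the canonical frame."""
    lm = landmarks.canonical()
    femoral_hinge, tibial_hinge = hinges or derive_hinges(lm)
    hip = rotate_about(lm.hip_center, femoral_hinge,
                       _FEMORAL_MATH_SIGN * rot.femoral)
    ankle = rotate_about(lm.ankle_center, tibial_hinge,
                         _TIBIAL_MATH_SIGN * rot.tibial)
    return replace(lm, hip_center=hip, ankle_center=ankle)


def measure_postop(landmarks: LimbLandmarks,
                   rot: FragmentRotation,
                   hinges: tuple[Point2, Point2] | None = None
                   ) -> tuple[float, float]:
    """(wbl_percent, jlo_plateau_angle) after applying the given rotations."""
    post = apply_rotations(landmarks, rot, hinges)
    stats = analyze(post)
    return stats.wbl_percent, stats.jlo_plateau_angle


def solve_vss(landmarks: LimbLandmarks,
              target_percent: float = 62.5,
              target_jlo: float = 88.0,
              hinges: tuple[Point2, Point2] | None = None,
              max_iter: int = 100) -> VSSResult:
    """Solve for the fragment rotations meeting both post-operative targets.

    Deterministic damped Newton from (0, 0) with a forward-difference
    Jacobian (step 0.01 degrees).  Converged means the residuals are within
    ``PERCENT_TOL`` (% of plateau width) and ``ANGLE_TOL`` (degrees).
    """
    lm = landmarks.canonical()
    hinges = hinges or derive_hinges(lm)
    pre = analyze(lm)
    if pre.wbl_percent > target_percent + 1e-6:
        raise UnsupportedDeformityError(
            "weight-bearing line already lateral to the target; "
            "valgus correction is unsupported")

    target = np.array([target_percent, target_jlo])

    def residual(x: np.ndarray) -> np.ndarray:
        rot = FragmentRotation(femoral=float(x[0]), tibial=float(x[1]))
        p, j = measure_postop(lm, rot, hinges)
        return np.array([p, j]) - target

    x = np.zeros(2)
    r = residual(x)
    eps = 0.01
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if abs(r[0]) <= PERCENT_TOL and abs(r[1]) <= ANGLE_TOL:
            break
        jac = np.empty((2, 2))
        for k in range(2):
            dx = np.zeros(2)
            dx[k] = eps
            jac[:, k] = (residual(x + dx) - r) / eps
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular Jacobian at iteration {iterations}",
                residuals=tuple(r), iterations=iterations) from exc
        lam = 1.0
        for _ in range(12):
            r_new = residual(x + lam * step)
            if np.linalg.norm(r_new) < np.linalg.norm(r):
                break
            lam *= 0.5
        x = x + lam * step
        r = r_new
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; residuals {tuple(r)}",
            residuals=tuple(r), iterations=max_iter)

    rot = FragmentRotation(femoral=float(x[0]), tibial=float(x[1]))
    post = apply_rotations(lm, rot, hinges)
    stats = analyze(post)
    return VSSResult(
        rotations=rot,
        postop_hip=post.hip_center,
        postop_ankle=post.ankle_center,
        achieved_percent=stats.wbl_percent,
        achieved_jlo_angle=stats.jlo_plateau_angle,
        converged=True,
        iterations=iterations,
    )


def vss_gaps(landmarks: LimbLandmarks,
             rot: FragmentRotation,
             construction: PlanConstruction) -> tuple[float, float]:
    """Wedge gaps for solver rotations, using the same cortex-intersection
    rule as the geometric planner (femoral gap at the lateral femoral
    cortex, tibial gap at the medial tibial cortex)."""
    lm = landmarks.canonical()
    femoral_gap, _ = _wedge_gap(
        construction.femoral_osteotomy, construction.femoral_hinge,
        _FEMORAL_MATH_SIGN * rot.femoral, lm.femoral_lateral_cortex)
    tibial_gap, _ = _wedge_gap(
        construction.tibial_osteotomy, construction.tibial_hinge,
        _TIBIAL_MATH_SIGN * rot.tibial, lm.tibial_medial_cortex)
    return femoral_gap, tibial_gap
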