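"""Parametric synthetic-limb generator and cohort factory.

Builds calibrated landmark sets with *prescribed* deformity: the tibial
plateau tangent is horizontal through the origin, the tibial mechanical
axis leaves the knee center at (90 − MPTA) degrees medial of vertical, the
femoral condylar tangent converges medially on the plateau by JLCA, and the
femoral mechanical axis leaves at (LDFA − 90) + JLCA degrees medial of
vertical, so that the analyzer recovers MPTA, LDFA and JLCA exactly (the
generator/analyzer round trip is the module's core contract).  HKA is
emergent from the three input angles, not sampled independently.

Cortices are straight lines offset perpendicular to the mechanical axes —
adequate for the osteotomy gap-intersection logic; no attempt is made to
render realistic bone contours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .geometry import Calibration, Point2
from .landmarks import LimbLandmarks

#: varus cohort deformity parameters: (mean, SD) in degrees
COHORT_DEFORMITY = {
    "mpta": (81.52, 1.86),
    "ldfa": (93.13, 1.49),
    "jlca": (4.05, 1.79),
}

#: normative (non-pathological) reference means
NORMATIVE_DEFORMITY = {
    "mpta": (85.6, 2.4),
    "ldfa": (85.8, 2.0),
    "jlca": (1.09, 0.9),
}

#: radiographic joint-space height between the condylar and plateau tangents, mm
JOINT_SPACE_MM = 6.0


@dataclass(frozen=True)
class LimbSpec:
    """Prescription for one synthetic limb (lengths in mm, angles in degrees)."""

    mpta: float = 81.52
    ldfa: float = 93.13
    jlca: float = 4.05
    femur_length: float = 430.0
    tibia_length: float = 370.0
    plateau_width: float = 78.0
    side: str = "right"
    #: (femoral, tibial) straight-cortex half-widths at the osteotomy levels
    cortical_half_widths: tuple[float, float] = (28.0, 32.0)
    seed: int = 0
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if min(self.femur_length, self.tibia_length, self.plateau_width) <= 0:
            raise GenerationError("lengths and widths must be positive")
        if min(self.cortical_half_widths) <= 0:
            raise GenerationError("cortical half widths must be positive")
        for name in ("mpta", "ldfa"):
            v = getattr(self, name)
            if not 45.0 < v < 135.0:
                raise GenerationError(f"{name}={v} outside (45, 135)")
        if abs(self.jlca) > 20.0:
            raise GenerationError(f"jlca={self.jlca} implausible")


def _axis_points(spec: LimbSpec):
    """Hip, ankle and tangent geometry in the canonical right-limb frame."""
    knee = np.zeros(2)
    w = spec.plateau_width
    plateau_medial = Point2(-w / 2.0, 0.0)
    plateau_lateral = Point2(w / 2.0, 0.0)

    # tibial mechanical axis: medial deviation of the ankle for MPTA < 90
    delta_t = math.radians(90.0 - spec.mpta)
    u_tib = np.array([-math.sin(delta_t), math.cos(delta_t)])
    ankle = knee + spec.tibia_length * u_tib

    # condylar tangent: converges medially by JLCA, joint space at the midline
    alpha = math.radians(spec.jlca)
    t_lat = np.array([math.cos(alpha), -math.sin(alpha)])
    c0 = np.array([0.0, -JOINT_SPACE_MM])
    condyle_medial = Point2(*(c0 - (w / 2.0) * t_lat))
    condyle_lateral = Point2(*(c0 + (w / 2.0) * t_lat))

    # femoral mechanical axis: medial deviation (LDFA-90)+JLCA of the hip
    phi_f = math.radians(spec.ldfa - 90.0) + alpha
    u_fem_up = np.array([-math.sin(phi_f), -math.cos(phi_f)])
    hip = knee + spec.femur_length * u_fem_up

    return plateau_medial, plateau_lateral, condyle_medial, condyle_lateral, hip, ankle, u_tib, u_fem_up


def generate_limb(spec: LimbSpec) -> LimbLandmarks:
    """Deterministically build the landmark set for one prescribed limb."""
    (plateau_medial, plateau_lateral, condyle_medial, condyle_lateral,
     hip, ankle, u_tib, u_fem_up) = _axis_points(spec)

    w_f, w_t = spec.cortical_half_widths

    # perpendiculars pointing medial (-x side) of each mechanical axis
    n_fem_med = np.array([u_fem_up[1], -u_fem_up[0]])
    if n_fem_med[0] > 0:
        n_fem_med = -n_fem_med
    n_tib_med = np.array([-u_tib[1], u_tib[0]])
    if n_tib_med[0] > 0:
        n_tib_med = -n_tib_med

    def seg(base, axis_dir, normal, offset, t0, t1):
        a = base + t0 * axis_dir + offset * normal
        b = base + t1 * axis_dir + offset * normal
        return (Point2(*a), Point2(*b))

    knee = np.zeros(2)
    fem_extent = (JOINT_SPACE_MM + 2.0, 0.5 * spec.femur_length)
    tib_extent = (4.0, 0.55 * spec.tibia_length)

    lm = LimbLandmarks(
        side="right",
        hip_center=Point2(*hip),
        plateau_medial=plateau_medial,
        plateau_lateral=plateau_lateral,
        condyle_medial=condyle_medial,
        condyle_lateral=condyle_lateral,
        ankle_center=Point2(*ankle),
        femoral_medial_cortex=seg(knee, u_fem_up, n_fem_med, w_f, *fem_extent),
        femoral_lateral_cortex=seg(knee, u_fem_up, -n_fem_med, w_f, *fem_extent),
        tibial_medial_cortex=seg(knee, u_tib, n_tib_med, w_t, *tib_extent),
        tibial_lateral_cortex=seg(knee, u_tib, -n_tib_med, w_t, *tib_extent),
        calibration=spec.calibration,
    )
    return lm.mirror() if spec.side == "left" else lm


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixture_f1(seed: int = 1) -> LimbLandmarks:
    """Moderate varus reference limb: MPTA 81.5, LDFA 93.1, JLCA 0."""
    return generate_limb(LimbSpec(mpta=81.5, ldfa=93.1, jlca=0.0, seed=seed))


def fixture_f2(seed: int = 2) -> LimbLandmarks:
    """Severe varus limb: MPTA 80, LDFA 94 (with typical intra-articular wear)."""
    return generate_limb(LimbSpec(mpta=80.0, ldfa=94.0, jlca=4.0, seed=seed))


def generate_aligned_limb(target_percent: float = 62.5,
                          jlo_angle: float = 88.0,
                          spec: LimbSpec | None = None) -> LimbLandmarks:
    """Limb whose Mikulicz line already crosses the plateau at
    ``target_percent`` with the given medial joint-line angle (JLCA = 0):
    the zero-correction fixed point of the planner."""
    base = spec or LimbSpec()
    w = base.plateau_width
    x_cp = (target_percent / 100.0 - 0.5) * w
    cot = math.cos(math.radians(jlo_angle)) / math.sin(math.radians(jlo_angle))
    # ankle on the axis: -Lt sin(d) = x_cp - cot * Lt cos(d)
    lt, lf = base.tibia_length, base.femur_length
    delta = _solve_angle(lambda d: -lt * math.sin(d) - x_cp + cot * lt * math.cos(d))
    phi = _solve_angle(lambda p: -lf * math.sin(p) - x_cp - cot * lf * math.cos(p))
    from dataclasses import replace

    spec_aligned = replace(base, mpta=90.0 - math.degrees(delta),
                           ldfa=90.0 + math.degrees(phi), jlca=0.0)
    return generate_limb(spec_aligned)


def _solve_angle(f, lo: float = -0.4, hi: float = 0.4) -> float:
    from scipy.optimize import brentq

    return float(brentq(f, lo, hi, xtol=1e-14))


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _eligible_angles(mpta: float, ldfa: float, jlca: float) -> bool:
    """Angle-level enrollment screen mirroring the varus-cohort inclusion
    and exclusion criteria (LDFA > 90, MPTA < 85, 0 <= JLCA <= 6)."""
    return ldfa > 90.0 and mpta < 85.0 and 0.0 <= jlca <= 6.0


def sample_cohort_specs(n: int = 23,
                        deformity: dict | None = None,
                        seed: int = 42,
                        max_resample: int = 100) -> list[LimbSpec]:
    """Draw limb prescriptions from truncated normal distributions.

    Each angle is drawn from N(mean, SD) truncated at +/- 3 SD; a draw
    violating the enrollment screen is resampled (an enrolled cohort is an
    inclusion-filtered sample, so rejection is the right emulation).
    """
    if n < 1:
        raise GenerationError("cohort size must be >= 1")
    pars = deformity or COHORT_DEFORMITY
    rng = np.random.default_rng(seed)

    def trunc_draw(mean, sd):
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if abs(v - mean) <= 3.0 * sd:
                return float(v)
        raise GenerationError("truncated-normal sampling exhausted")

    specs: list[LimbSpec] = []
    for i in range(n):
        for attempt in range(max_resample):
            mpta = trunc_draw(*pars["mpta"])
            ldfa = trunc_draw(*pars["ldfa"])
            jlca = trunc_draw(*pars["jlca"])
            if _eligible_angles(mpta, ldfa, jlca):
                specs.append(LimbSpec(mpta=mpta, ldfa=ldfa, jlca=jlca, seed=seed + i))
                break
        else:
            raise GenerationError(
                f"could not draw an eligible limb in {max_resample} attempts")
    return specs


def generate_cohort(n: int = 23,
                    deformity: dict | None = None,
                    seed: int = 42) -> list[LimbLandmarks]:
    """Generate a cohort of varus limbs emulating the enrolled population."""
    return [generate_limb(s) for s in sample_cohort_specs(n, deformity, seed)]
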