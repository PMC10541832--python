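# Methods

## Coordinate frame and conventions

All computation runs in the radiograph display frame: x to the image
right, y downward, millimetres after calibration (pixel coordinates are
multiplied by the `mm_per_pixel` scale derived from a 100 × 100 mm
reference square).  "Parallel to the ground" means constant y.  Internally
every operation canonicalizes to a right-limb frame in which the tibial
medial side is toward −x; a left limb is mirrored about a vertical axis on
the way in and mirrored back for rendering.  This gives one code path and a
testable mirror-symmetry invariant.  Angles cross the API in degrees.

Sign conventions: HKA is reported as deviation from 180° with varus
positive; JLCA is positive when the condylar and plateau tangents converge
medially (varus wear); fragment rotations are stored wedge-positive
(femoral closing, tibial opening).

The knee center of *both* mechanical axes is the midpoint of the tibial
plateau tangent.  The choice makes HKA the angle between the hip→knee and
knee→ankle axes and keeps MPTA, LDFA, JLCA and HKA mutually consistent:
for generated limbs the identity HKA = (90 − MPTA) + (LDFA − 90) + JLCA
holds exactly.  Clinical software that uses separate femoral and tibial
knee centers absorbs part of the JLCA into the gap between the axes and
reports correspondingly smaller HKA values; nothing downstream of the
planner depends on that difference.

## The planning construction

Given the landmark set, the planner:

1. places the **correction point** on the plateau tangent at
   `target_percent` (default 62.5 %) of plateau width from the medial
   edge — the point the post-operative weight-bearing line should cross;
2. draws the **new loading axis** through that point at the prescribed
   medial-inferior angle to the plateau tangent (`nmjl_angle`, default
   88°).  The axis is *not* forced vertical: the construction's premise is
   that the joint-line angle, not verticality, is fixed, and the plateau
   tangent (the fixed fragment) is the reference.  This is the single most
   consequential interpretation in the package: the prescription "draw a
   vertical line subtending 88°" is self-contradictory for an oblique
   plateau, and only the angle prescription survives contact with the
   fixed-fragment geometry;
3. derives the **hinge points** (unless given explicitly as landmarks):
   the tibial hinge on the lateral tibial cortex 15 mm (vertical drop)
   below the lateral plateau edge, near the fibular head; the femoral
   hinge on the medial femoral cortex 40 mm proximal to the medial
   condylar tangent point, in the adductor-tubercle region.  The femoral
   location is a verbal anatomic description only, so the 40 mm default is
   a configurable judgment call;
4. measures the **femoral correction angle** at the femoral hinge between
   the A-line (hinge → hip center) and the B-line (hinge → intersection of
   the new axis with the horizontal through the hip center), and the
   **tibial correction angle** at the tibial hinge between the C-line
   (hinge → ankle center) and the D-line (hinge → intersection of the new
   axis with the horizontal through the ankle center);
5. draws the **osteotomy lines** — femoral: through the femoral hinge at
   20° (configurable) to the perpendicular of the femoral mechanical axis,
   descending lateral → medial; tibial: from the medial-cortex entry point
   40 mm below the joint line to the tibial hinge — swings each line about
   its hinge by the corresponding correction angle, and reads the **wedge
   gap** as the distance between the two intersections with the straight
   cortex line (lateral femoral cortex for the closing wedge, medial
   tibial cortex for the opening wedge).  On a cortex perpendicular to the
   cut this rule gives W·tanθ, within 1 % of the chord 2·W·sin(θ/2) for
   the clinically planned wedge range (θ ≲ 10°).

Soft tissue: a JLCA above 2° flags an intra-articular share of the
deformity that rigid bone correction would overcorrect.  When enabled
(default), the planner deducts (JLCA − 2)/2 degrees — entirely from the
femoral angle, because the plateau tangent is the method's joint-line
reference — after angle derivation and before gap computation; the gap is
recomputed by re-rotating the osteotomy line with the adjusted angle
(exact), not by linear scaling.  The deduction is floored at zero with a
warning if it exceeds the femoral correction.  Uncalibrated inputs have
their gaps inflated by the customary 3 %.

Eligibility (all strict inequalities, as used clinically): LDFA > 90 and
MPTA < 85, together with either a single-HTO plan overcorrecting MPTA
beyond 94° or a total correction > 10° / any gap > 15 mm; JLCA > 6°
excludes.  The single-HTO check is Miniaci-style: the desired axis runs
from the unmoved hip center through the correction point, and the post-op
MPTA is predicted additively as pre-op MPTA + hinge correction angle.

## The rigid-fragment simulator

The simulator replaces interactive virtual-segmentation dragging with a
deterministic root-finder.  The knee block between the two osteotomies is
the static reference; a femoral rotation swings the hip about the femoral
hinge and a tibial rotation swings the ankle about the tibial hinge
(fragments are independent, so the order is immaterial).  A damped Newton
iteration from (0, 0) with a forward-difference Jacobian (step 0.01°)
solves the 2 × 2 system {WBL % = target, joint-line angle = target};
convergence tolerances are 0.05 % of plateau width and 0.01°, an order of
magnitude below reported human measurement error (< 1° / < 2 mm).  On
cohort limbs it converges in ≤ 5 iterations.  The simulator does not model
soft tissue, so planner-vs-simulator comparisons are run with the JLCA
deduction disabled (bone-only corrections are the commensurable quantity).

## Accuracy of the construction (known limitation)

The hinge construction is a small-angle approximation of the rigid
rotation: rotating a fragment by the A–B (or C–D) angle carries the hip
(ankle) onto the B (D) *ray* at its pre-operative hinge radius, whereas
the axis target point sits at a slightly different radius.  The residual
perpendicular offset (≈ 0.4 mm femur, ≈ 0.5 mm tibia at mid-cohort
deformity with metaphyseal hinge offsets of 28 / 32 mm) leaves the
simulated post-operative joint-line angle within ±0.03° of target but
shifts the weight-bearing-line crossing systematically ~0.5–0.8 % of
plateau width medial of it.  The error grows with the hinge's lateral
offset from the mechanical axis and with deformity magnitude, and
vanishes as either goes to zero; in angle terms the planner stays within
0.15° per level of the exact solver across the cohort deformity range.
The same radius effect makes the additive single-HTO MPTA prediction
overestimate the simulated post-op MPTA by the factor
|hinge − ankle| / |knee − ankle| (≈ 4 % of the correction).

## Synthetic limbs and what they do (not) show

The generator builds limbs analytically: plateau tangent horizontal
through the origin; tibial mechanical axis leaving the knee center at
(90 − MPTA) medial of vertical; condylar tangent converging medially by
JLCA above a 6 mm joint space; femoral mechanical axis at
(LDFA − 90) + JLCA medial of vertical; straight cortices offset
perpendicular to the mechanical axes (femur 28 mm, tibia 32 mm — distal
femoral / proximal tibial metaphyseal half-widths at the osteotomy
levels).  Segment lengths default to femur 430 mm, tibia 370 mm, plateau
width 78 mm.  The analyzer recovers the prescribed angles to < 0.05°
(round-trip contract); HKA is emergent, not sampled.

The cohort factory draws MPTA / LDFA / JLCA independently from normal
distributions truncated at ±3 SD (varus-cohort means/SDs above) and
rejects draws failing the enrollment screen (LDFA > 90, MPTA < 85,
0 ≤ JLCA ≤ 6), emulating an inclusion-filtered series; rejection shifts
the JLCA mean ~0.4° below its nominal value, as truncating a pathological
tail must.

Synthetic limbs have straight cortices, no osteophytes, no bone contour,
and exactly consistent landmarks.  Passing tests therefore demonstrate the
*geometric* fidelity of the constructions and the statistics, not
robustness to landmarking noise, image distortion, or anatomic variation
beyond the modeled parameters.

## Numerical choices

Parallelism/collinearity tolerance 1e-12 on normalized cross products;
rotations below 1e-9° treated as identity (gap exactly 0 iff the
correction is 0); planner rejects limbs whose weight-bearing line is
already at/lateral to the target (valgus) rather than mis-planning them.
File serialization rounds to 4 decimals (reports display 0.1 precision);
JSON output is written atomically (temp file + rename) with sorted keys so
identical inputs give byte-identical files.  ICC confidence intervals use
the F-based two-way random absolute-agreement form; Bland–Altman limits
use the sample (n − 1) SD and normal-theory CIs.  ICC reliability bands
assign boundary values to the lower band (strictly-greater thresholds at
0.5 / 0.75 / 0.9).  Problem sizes throughout (23-limb cohorts, a 3 × 3
deformity grid at three scales, 1000-draw sampling checks) keep the full
suite and the validation script in the seconds range on one CPU.
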