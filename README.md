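# dloplan

Geometric planning of **double-level knee osteotomies** (combined distal
femoral + high tibial osteotomy, DLO) from calibrated 2D landmarks of a
standing long-leg AP radiograph.

Severe varus malalignment often combines a femoral deformity (LDFA > 90°)
with a tibial one (MPTA < 85°).  Correcting it at a single level restores
the hip–knee–ankle axis but tilts the knee joint line, so the correction
must be split across both bones.  `dloplan` implements a planning
construction that works *backwards from the desired post-operative joint
line obliquity*: the planner fixes where the new weight-bearing line should
cross the tibial plateau (default 62.5 % of plateau width from the medial
edge, a Fujisawa-type target) and what medial angle it should subtend with
the plateau tangent (default 88°), then reads the femoral and tibial
correction angles off two hinge constructions and converts them to
millimetric wedge gaps at the cortices.

The package contains, as first-class tested code:

- **`deformity`** — Paley-style mechanical analysis: HKA deviation, MPTA,
  LDFA, JLCA, the Mikulicz line, its plateau crossing (WBL %), and the
  joint-line-obliquity indices (plateau angle and M-JL angle);
- **`planning`** — the geometric planner: correction point, new loading
  axis, hinge points, A/B/C/D lines, correction angles, oblique osteotomy
  lines and wedge gaps; the (JLCA − 2)/2 soft-tissue deduction; the 3 %
  uncalibrated-gap increment; the Miniaci-style single-HTO check and the
  DLO eligibility screen;
- **`simulation`** — an exact rigid-fragment virtual-osteotomy simulator
  (hip and ankle fragments rotate about the hinge points; the knee block is
  fixed) with a damped-Newton solver that hits both post-operative targets
  to machine-level tolerance — the oracle the planner is validated against;
- **`synthetic`** — a parametric limb generator with prescribed MPTA /
  LDFA / JLCA and a truncated-normal varus cohort factory (defaults: MPTA
  81.52 ± 1.86, LDFA 93.13 ± 1.49, JLCA 4.05 ± 1.79, n = 23);
- **`agreement`** — method-comparison statistics from first principles:
  ICC(2,1) (two-way random, absolute agreement, with F-based 95 % CI),
  Pearson r, and Bland–Altman bias / limits of agreement;
- **`io_json` / `svg_render` / `cli`** — a validated JSON landmark format,
  SVG overlays of the construction, and a thin `dloplan` command
  (`analyze`, `plan`, `simulate`, `cohort`, `agree`, `render`).

## Worked example

```bash
python examples/simulate_correction.py
```

```
               geometric plan   exact solver
femoral angle         7.12 deg         7.18 deg
tibial angle          8.19 deg         8.27 deg
femoral gap           7.57 mm          7.64 mm
tibial gap           12.96 mm         13.10 mm

applying the plan's rotations: WBL 61.90 % (target 62.5), joint line 87.99 deg (target 88)
solver converged in 3 iterations at 62.500 % / 88.000 deg
```

For a varus limb with MPTA 81.5° and LDFA 93.1°, the desk construction
prescribes a 7.1° lateral closing wedge of the femur (7.6 mm at the lateral
cortex) and an 8.2° medial opening wedge of the tibia (13.0 mm at the
medial cortex).  The exact simulator agrees to well under 0.1° per level;
applying the planned rotations rigidly reproduces the 88° target joint-line
angle almost exactly and the plateau crossing to ~0.6 % of plateau width
(the small systematic shortfall of the hinge construction — see
`docs/methods.md`).

Other examples: `analyze_limb.py` (deformity analysis),
`plan_dlo.py` (full plan + eligibility screen),
`cohort_agreement.py` (ICC / Bland–Altman between planner and simulator on
a 23-limb synthetic cohort), `render_plan.py` (SVG overlay).

The same functionality is available from the shell:

```bash
dloplan cohort --n 23 --seed 42 --out-dir cohort/
dloplan plan cohort/L01.json --svg L01.svg
```

## Scope

The package operates on measured landmark coordinates only: it does not
segment radiographs, detect landmarks, read DICOM pixel data, or address
sagittal-plane parameters, limb-length discrepancy, or implant selection.
Valgus limbs are rejected rather than mis-planned.
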