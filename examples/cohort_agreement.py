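"""Method-comparison statistics on a synthetic 23-limb varus cohort.

Treats the geometric planner and the exact rigid solver as two raters of
the same limbs and computes ICC(2,1), Pearson r and Bland-Altman limits of
agreement for the femoral and tibial correction angles and gaps.
"""

import numpy as np

from dloplan import (
    PlanParameters,
    compare_methods,
    generate_cohort,
    interpret_icc,
    plan_nmjl,
    solve_vss,
    vss_gaps,
)

cohort = generate_cohort(n=23, seed=42)
params = PlanParameters(apply_jlca_adjustment=False)

series = {"femoral angle (deg)": [], "tibial angle (deg)": [],
          "femoral gap (mm)": [], "tibial gap (mm)": []}
for limb in cohort:
    plan = plan_nmjl(limb, params)
    exact = solve_vss(limb)
    fgap, tgap = vss_gaps(limb, exact.rotations, plan.construction)
    series["femoral angle (deg)"].append((plan.femoral_correction,
                                          exact.rotations.femoral))
    series["tibial angle (deg)"].append((plan.tibial_correction,
                                         exact.rotations.tibial))
    series["femoral gap (mm)"].append((plan.femoral_gap, fgap))
    series["tibial gap (mm)"].append((plan.tibial_gap, tgap))

print(f"{'measure':22s} {'ICC(2,1)':>9s} {'r':>7s} {'bias':>7s} {'LoA':>16s}")
for name, pairs in series.items():
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    res = compare_methods(x, y, label=name)
    lo, hi = res.ba_loa
    print(f"{name:22s} {res.icc:9.4f} {res.pearson_r:7.4f} "
          f"{res.ba_bias:+7.3f} [{lo:+6.3f}, {hi:+6.3f}]  "
          f"({interpret_icc(res.icc)})")

print()
print("ICC near 1 with a bias well under measurement precision means the"
      " desk construction and the segmentation-style simulation agree on"
      " every limb of the cohort.")
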