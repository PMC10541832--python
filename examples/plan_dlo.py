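"""Double-level osteotomy plan for the reference varus limb.

Runs the geometric construction at the default protocol (correction point
62.5 % of plateau width, post-operative medial joint-line angle 88 deg) and
prints the correction angles, wedge gaps and the eligibility screen.
"""

from dloplan import (
    check_eligibility,
    fixture_f2,
    plan_nmjl,
    plan_single_hto,
)

limb = fixture_f2()  # severe varus: MPTA 80, LDFA 94, JLCA 4
plan = plan_nmjl(limb)
hto = plan_single_hto(limb)
verdict = check_eligibility(plan.analysis, hto, plan)

print(f"femoral correction  {plan.femoral_correction:5.1f} deg "
      f"(lateral closing wedge, {plan.femoral_gap:4.1f} mm resected)")
print(f"tibial correction   {plan.tibial_correction:5.1f} deg "
      f"(medial opening wedge, {plan.tibial_gap:4.1f} mm opened)")
print(f"soft-tissue deduction (JLCA rule): {plan.jlca_adjustment:4.2f} deg "
      "taken off the femur")
print(f"single-HTO check: post-op MPTA would be {hto[1]:5.1f} deg")
print(f"double-level indicated: {verdict.dlo_indicated}")
print()
print("The femoral wedge closes laterally and the tibial wedge opens"
      " medially; a single tibial osteotomy would overcorrect the plateau"
      " beyond MPTA 94, which is exactly the double-level indication.")
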