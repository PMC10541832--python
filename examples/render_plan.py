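"""Render the planning construction as an SVG overlay.

Writes `plan_f1.svg` in the working directory: plateau and condylar
tangents, cortices, pre-operative Mikulicz line, the new loading axis, the
A/B/C/D hinge lines, both osteotomies with their swung twins and the wedge
gap chords.
"""

from dloplan import fixture_f1, plan_nmjl
from dloplan.svg_render import write_plan_svg

limb = fixture_f1()
plan = plan_nmjl(limb)
write_plan_svg(limb, plan, "plan_f1.svg")
print(f"wrote plan_f1.svg "
      f"(femur {plan.femoral_correction:.1f} deg / {plan.femoral_gap:.1f} mm, "
      f"tibia {plan.tibial_correction:.1f} deg / {plan.tibial_gap:.1f} mm)")
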