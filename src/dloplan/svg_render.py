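"""SVG overlay of a planning construction.

Draws the bone landmarks, the Mikulicz line, the new loading axis, the
A/B/C/D construction lines, both osteotomy lines with their swung twins and
the wedge gap chords — a vector figure in the style of planning drawings.
Pure stdlib XML; the radiograph display frame (y down) matches SVG natively.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .geometry import Line2, Point2, intersect, project_param
from .landmarks import LimbLandmarks
from .planning import PlanResult

_COLORS = {
    "bone": "#444444",
    "mikulicz": "#888888",
    "new_axis": "#1f77b4",
    "ab": "#d62728",
    "cd": "#9467bd",
    "osteotomy": "#2ca02c",
    "gap": "#17becf",
}


def _seg(parent, a: Point2, b: Point2, color: str, width: float = 1.2,
         dash: str | None = None) -> None:
    attrs = {
        "x1": f"{a.x:.2f}", "y1": f"{a.y:.2f}",
        "x2": f"{b.x:.2f}", "y2": f"{b.y:.2f}",
        "stroke": color, "stroke-width": f"{width}",
    }
    if dash:
        attrs["stroke-dasharray"] = dash
    ET.SubElement(parent, "line", attrs)


def _dot(parent, p: Point2, color: str = "#000000", r: float = 2.5) -> None:
    ET.SubElement(parent, "circle", {
        "cx": f"{p.x:.2f}", "cy": f"{p.y:.2f}", "r": f"{r}",
        "fill": color,
    })


def _clip(line: Line2, t0: float, t1: float) -> tuple[Point2, Point2]:
    return line.point_at(t0), line.point_at(t1)


def render_plan_svg(landmarks: LimbLandmarks, plan: PlanResult) -> str:
    """Return the SVG text for one planned limb.

    The construction is computed in the canonical right-limb frame; a left
    limb is mirrored back to its display orientation before drawing.
    """
    lm = landmarks.canonical()
    c = plan.construction
    mirror = landmarks.side == "left"

    def m(p: Point2) -> Point2:
        return p.mirrored() if mirror else p

    def ml(line: Line2) -> Line2:
        return line.mirrored() if mirror else line

    pts = [lm.hip_center, lm.ankle_center, lm.plateau_medial, lm.plateau_lateral,
           lm.condyle_medial, lm.condyle_lateral, c.femoral_hinge, c.tibial_hinge]
    pts = [m(p) for p in pts]
    xs = [p.x for p in pts]
    ys = [p.y for p in pts]
    pad = 60.0
    x0, y0 = min(xs) - pad, min(ys) - pad
    w, h = max(xs) - min(xs) + 2 * pad, max(ys) - min(ys) + 2 * pad

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "viewBox": f"{x0:.1f} {y0:.1f} {w:.1f} {h:.1f}",
        "width": f"{w:.0f}", "height": f"{h:.0f}",
    })

    # bone axes and tangents
    _seg(svg, m(lm.plateau_medial), m(lm.plateau_lateral), _COLORS["bone"], 2.0)
    _seg(svg, m(lm.condyle_medial), m(lm.condyle_lateral), _COLORS["bone"], 2.0)
    for seg in (lm.femoral_medial_cortex, lm.femoral_lateral_cortex,
                lm.tibial_medial_cortex, lm.tibial_lateral_cortex):
        _seg(svg, m(seg[0]), m(seg[1]), _COLORS["bone"], 0.8, dash="4 3")

    # Mikulicz line (pre-op) and the new loading axis
    mik = Line2.through(lm.hip_center, lm.ankle_center)
    a, b = _clip(mik, -30.0, project_param(mik, lm.ankle_center) + 30.0)
    _seg(svg, m(a), m(b), _COLORS["mikulicz"], 1.0, dash="6 4")
    t_hip = project_param(c.new_axis, lm.hip_center)
    t_ank = project_param(c.new_axis, lm.ankle_center)
    a, b = _clip(c.new_axis, min(t_hip, t_ank) - 30.0, max(t_hip, t_ank) + 30.0)
    _seg(svg, m(a), m(b), _COLORS["new_axis"], 1.6)

    # A/B and C/D hinge lines
    for line, ref in ((c.line_A, lm.hip_center), (c.line_B, lm.hip_center)):
        _seg(svg, m(line.origin), m(line.point_at(project_param(line, ref))),
             _COLORS["ab"], 1.0)
    for line, ref in ((c.line_C, lm.ankle_center), (c.line_D, lm.ankle_center)):
        _seg(svg, m(line.origin), m(line.point_at(project_param(line, ref))),
             _COLORS["cd"], 1.0)

    # osteotomies, their swung twins and the gap chords
    for osteo, rotated, cortex in (
        (c.femoral_osteotomy, c.rotated_femoral_osteotomy, lm.femoral_lateral_cortex),
        (c.tibial_osteotomy, c.rotated_tibial_osteotomy, lm.tibial_medial_cortex),
    ):
        cortex_line = Line2.through(cortex[0], cortex[1])
        g1 = intersect(osteo, cortex_line)
        _seg(svg, m(osteo.origin), m(g1), _COLORS["osteotomy"], 1.6)
        try:
            g2 = intersect(rotated, cortex_line)
        except Exception:
            g2 = g1
        _seg(svg, m(rotated.origin), m(g2), _COLORS["osteotomy"], 1.2, dash="5 3")
        _seg(svg, m(g1), m(g2), _COLORS["gap"], 2.2)

    for p in (lm.hip_center, lm.ankle_center, c.correction_point,
              c.femoral_hinge, c.tibial_hinge):
        _dot(svg, m(p))

    label = ET.SubElement(svg, "text", {
        "x": f"{x0 + 8:.1f}", "y": f"{y0 + 18:.1f}", "font-size": "14",
        "font-family": "sans-serif", "fill": "#000000",
    })
    label.text = (f"femur {plan.femoral_correction:.1f} deg / "
                  f"{plan.femoral_gap:.1f} mm close — "
                  f"tibia {plan.tibial_correction:.1f} deg / "
                  f"{plan.tibial_gap:.1f} mm open")

    return ET.tostring(svg, encoding="unicode")


def write_plan_svg(landmarks: LimbLandmarks, plan: PlanResult, path) -> None:
    text = render_plan_svg(landmarks, plan)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text + "\n")
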