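"""Deformity analysis of a synthetic varus limb.

Builds a limb with a prescribed tibial/femoral/intra-articular deformity and
runs the mechanical angle analysis.  The printed angles should reproduce the
generator inputs; HKA and the weight-bearing-line crossing are emergent.
"""

from dloplan import LimbSpec, analyze, generate_limb

limb = generate_limb(LimbSpec(mpta=81.52, ldfa=93.13, jlca=4.05))
st = analyze(limb)

print(f"MPTA              {st.mpta:6.2f} deg   (tibial varus: < 87)")
print(f"LDFA              {st.ldfa:6.2f} deg   (femoral varus: > 90)")
print(f"JLCA              {st.jlca:6.2f} deg   (medial convergence)")
print(f"HKA deviation     {st.hka_deviation:6.2f} deg   (varus positive)")
print(f"WBL crossing      {st.wbl_percent:6.2f} %     (50 = plateau center)")
print(f"joint-line angle  {st.jlo_plateau_angle:6.2f} deg   (Mikulicz vs plateau)")
print(f"M-JL angle        {st.mjl_angle:6.2f} deg   (Mikulicz vs JLCA bisector)")
print()
print("A WBL crossing far medial of 50% (negative values fall medial of the"
      " plateau edge itself) with MPTA < 85 and LDFA > 90 is the classic"
      " double-level varus pattern.")
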