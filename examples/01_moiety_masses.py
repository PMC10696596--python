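"""Why sulfo- and phosphotyrosine are so hard to tell apart by mass.

Computes both modification deltas from atomic composition and the m/z
separation they produce on a typical doubly charged tryptic peptide.
"""

from sulfoscan import mod_delta_mass, mz_from_mass, parse_peptide, peptide_neutral_mass

sulfo = mod_delta_mass("sulfo")
phospho = mod_delta_mass("phospho")
print(f"sulfation   (+SO3):  {sulfo:.6f} Da")
print(f"phosphorylation (+HPO3): {phospho:.6f} Da")
print(f"difference: {1000 * (phospho - sulfo):.3f} mDa")

sy = parse_peptide("EDFED[sY]EFDGK")
py = parse_peptide("EDFED[pY]EFDGK")
mz_sy = mz_from_mass(peptide_neutral_mass(sy), 2)
mz_py = mz_from_mass(peptide_neutral_mass(py), 2)
print(f"\nEDFED[sY]EFDGK 2+ : {mz_sy:.5f} m/z")
print(f"EDFED[pY]EFDGK 2+ : {mz_py:.5f} m/z")
print(f"separation: {(mz_py - mz_sy) / mz_sy * 1e6:.1f} ppm")
print("-> at a 25 ppm tolerance the two precursors are indistinguishable;")
print("   discrimination must come from gas-phase behavior, not mass.")
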