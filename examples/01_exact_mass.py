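"""Exact-mass arithmetic: formulas, adduct m/z, ppm error, isotope patterns.

Computes the theoretical ion masses the screening stage matches against.
"""

from phytoscreen import adduct_mz, isotope_pattern, monoisotopic_mass, parse_formula, ppm_error

# succinic acid, the earliest-eluting constituent of the formulation
counts = parse_formula("C4H6O4")
print(f"monoisotopic mass of C4H6O4: {monoisotopic_mass(counts):.6f} Da")
print(f"[M-H]-  m/z: {adduct_mz(counts, '[M-H]-'):.4f}")

# the sodiated phthalide senkyunolide I: the ~0.55 mDa electron term matters
senk = parse_formula("C12H16O4")
print(f"senkyunolide I [M+Na]+ m/z: {adduct_mz(senk, '[M+Na]+'):.4f}")

# a measured ophiopogonin D precursor vs its theoretical mass, in ppm
theo = adduct_mz(parse_formula("C44H70O16"), "[M-H]-")
print(f"ophiopogonin D found 853.4596 vs theory {theo:.4f}: "
      f"{ppm_error(853.4596, theo):+.1f} ppm")

# isotope envelope of the deprotonated ion: the M+1/M and M+2/M ratios are
# the second component of the screening score
pattern = isotope_pattern(parse_formula("C44H69O16"))
for k, ratio in pattern.binned:
    print(f"  M+{k}: {ratio:.4f}")
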