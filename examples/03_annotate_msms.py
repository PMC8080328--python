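"""Neutral-loss MS/MS annotation of a triterpenoid saponin.

Explains the published fragment ions of ophiopogonin D by glycoside losses:
each peak is matched to the closest combination of class-appropriate neutral
losses from the theoretical precursor m/z.
"""

from phytoscreen import ADDUCTS, MSMSSpectrum, TheoreticalIon, explain_fragments
from phytoscreen.chem import adduct_mz, isotope_pattern, parse_formula
from phytoscreen.database import CompoundRecord

rec = CompoundRecord(
    name="Ophiopogonin D",
    formula=tuple(sorted(parse_formula("C44H70O16").items())),
    sources=frozenset({"OJ"}),
    compound_class="triterpenoid_saponin",
)
adduct = ADDUCTS["[M-H]-"]
ion = TheoreticalIon(
    compound=rec,
    adduct=adduct,
    mz=adduct_mz(rec.counts, adduct),
    pattern=isotope_pattern(adduct.ion_counts(rec.counts)),
)

spectrum = MSMSSpectrum(
    precursor_mz=853.4596,
    polarity="negative",
    peaks=((575.3584, 40.0), (721.4158, 85.0), (853.4574, 100.0)),
)

print(f"precursor theory: {ion.mz:.4f} [M-H]-")
for ann in explain_fragments(ion, spectrum):
    path = "+".join(l.name for l in ann.loss_path) or "(survivor ion)"
    print(f"  {ann.observed_mz:.4f}  ->  {ann.label('[M-H]-'):<18} "
          f"loss {path:<10} theory {ann.theoretical_mz:.4f} "
          f"({ann.error_ppm:+.1f} ppm)")
print("the 575.3584 peak is a pentose+deoxyhexose loss by mass -- 'Xyl' and")
print("'Rha' name 132/146 Da mass classes, not stereochemistry")
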