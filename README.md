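# phytoscreen

Database-driven annotation of LC-MS/MS data from multi-herb formulations, and
of the absorbed prototypes those formulations leave in plasma.

Untargeted characterization of a traditional-medicine preparation such as
Yiganmingmu (YGMM) oral liquid — twelve herbs, hundreds of constituents —
is usually driven by a *self-built components database*: a literature-mined
table of (compound name, molecular formula, source herb) for every herb in
the prescription. High-resolution Q-TOF features are screened against the
theoretical adduct masses of that table, candidate calls are confirmed by
their MS/MS neutral-loss patterns, and the confirmed constituents are then
re-found ("prototypes") in post-dose plasma by serum pharmacochemistry.
`phytoscreen` implements that whole workflow as a tested Python library for
analysts who want the screening logic to be reproducible and auditable
rather than buried in vendor software, plus a ground-truth synthetic-study
generator so every stage can be benchmarked without instrument data.

## The method

**Exact masses.** For a neutral molecule M with element counts $n_e$, the
monoisotopic mass is $M = \sum_e n_e m_e$ over lightest-isotope masses, and
an adduct ion's m/z is electron-aware:

$$ m/z = \frac{M + \Delta M_\text{adduct} + \Delta n_{e^-} \, m_{e^-}}{|z|} $$

so $[\mathrm{M{+}H}]^+$ adds a proton (1.007276 Da), not a hydrogen atom.
Registered adducts: $[\mathrm{M{+}H}]^+$, $[\mathrm{M{+}Na}]^+$,
$[\mathrm{M{+}K}]^+$ (positive mode); $[\mathrm{M{-}H}]^-$,
$[\mathrm{M{+}Cl}]^-$, $[\mathrm{M{+}HCOO}]^-$ (negative mode).

**Screening.** A feature matches a theoretical ion when
$|\delta| \le 10$ ppm, where $\delta = (m_\text{obs}-m_\text{theo})/m_\text{theo}\cdot 10^6$.
Match quality is the weighted combined score

$$ S = 0.6\,(1 - |\delta|/10) + 0.4\,\max(0,\, 1 - d_\text{iso}/0.10), $$

with $d_\text{iso}$ the mean relative deviation of the observed M+1/M and
M+2/M isotope ratios from the pattern predicted by per-element multinomial
convolution. A compound becomes a *candidate* as soon as one of its adduct
ions matches one feature; the score threshold (default 0.70) gates the
reported match list.

**MS/MS annotation.** Fragments are explained by breadth-first search over
multisets (depth ≤ 3) of class-appropriate neutral losses — H2O, CO, CO2,
CH3, CH2O, hexose 162.0528, deoxyhexose 146.0579, pentose 132.0423,
glucuronide, cross-ring sugar cleavages, acyl groups — plus the diagnostic
retro-Diels–Alder A/B-ring ions of flavonoids (m/z 151.0032 / 135.0449 in
negative mode). Each peak takes the minimum-|error| explanation within
10 ppm (2 mDa floor). Identifications are graded `standard_confirmed`
(reference standard, retention time match, ≥ 1 explained fragment),
`tentative` (≥ 1 explained fragment) or `candidate_only`.

**Prototype matching.** An identification is called an absorbed prototype
when a dosed-plasma feature matches it within 0.2 min and 10 ppm, shares
≥ 1 MS/MS fragment when plasma MS/MS exists, and is ≥ 3× more intense than
any blank-plasma feature in the same window.

The package ships a curated 117-entry identification table for YGMM
(formula, adduct, printed theoretical/found m/z, fragment labels, source
herbs, reference-standard and prototype flags) that doubles as the default
components database and as the reference for the exact-mass regression
tests.

## Worked example

`examples/03_annotate_msms.py` annotates the published fragment ions of the
saponin ophiopogonin D (C44H70O16, $[\mathrm{M{-}H}]^-$):

```
precursor theory: 853.4591 [M-H]-
  575.3584  ->  [M-H-Rha-Xyl]-     loss Rha+Xyl    theory 575.3589 (-0.9 ppm)
  721.4158  ->  [M-H-Xyl]-         loss Xyl        theory 721.4169 (-1.5 ppm)
  853.4574  ->  [M-H]-             loss (survivor ion) theory 853.4591 (-2.0 ppm)
```

The 721.4158 peak is a single pentose loss (132.0423 Da) from the precursor;
575.3584 is a pentose *plus deoxyhexose* loss by mass — the engine follows
the mass arithmetic even where published bracket labels are inconsistent.
Sugar names denote mass classes (Xyl ≡ Arb, Glc ≡ Gal), since MS cannot
distinguish stereoisomeric sugars.

The other examples cover exact-mass arithmetic (`01`), formulation screening
with decoys (`02`), the full plasma workflow (`04`) and a 667-compound
recovery benchmark (`05`); each prints the quantities it computes and what
they mean. The same stages are available from the shell:

```bash
phytoscreen simulate --seed 9 --n-compounds 30 --out-dir data/
phytoscreen screen --features data/formulation_features.csv --out cands.csv
phytoscreen annotate --features data/formulation_features.csv \
    --candidates cands.csv --mgf data/formulation.mgf --out ids.csv
phytoscreen match-plasma --identifications ids.csv \
    --plasma-features data/plasma_features.csv --out prototypes.csv
phytoscreen run-all --seed 4 --out-dir out/   # whole pipeline + recovery report
```

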