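# Methods

This note documents the models, parameter choices and numerical conventions
behind `phytoscreen`, and what the synthetic benchmarks do and do not show.

## Exact-mass kernel

Isotope masses and abundances are a single table compiled into
`phytoscreen.elements` (IUPAC/CIAAW 2021 atomic masses to ≥ 6 decimal
places) for C, H, N, O, F, Na, P, S, Cl and K. Formulas are plain Hill
strings — no isotope labels, charges or parenthesised groups, matching how
components databases print them.

Ion m/z values include the electron term
($m_{e^-} = 5.48580\times10^{-4}$ Da, $\Delta n_{e^-} = \mp 1$ for singly
charged cations/anions). This is not a nicety: the sodiated phthalide
senkyunolide I prints 247.0941, which only reproduces when the electron is
subtracted; electron-blind arithmetic is ~2 ppm off at that mass. Charge
states $|z| > 1$ and in-source fragments treated as adducts are out of
scope.

Isotope patterns are computed in fine structure: each element's
n-atom distribution is built by binary-exponentiation convolution of the
single-atom natural-abundance distribution, elements are convolved
together, coincident peaks (within $10^{-7}$ Da) are merged by
abundance-weighted centroid, and peaks below `prune_threshold` (default
$10^{-5}$ of the base peak; convolution uses a 10× finer working threshold)
are dropped. Peaks are then binned into nominal offsets M, M+1, M+2
(`max_bins = 3` — what a Q-TOF isotope-ratio score can actually use). The
bin window is anchored at the lightest peak; the full fine-structure list
keeps the base peak even for heavy-isotope-dominated species (e.g.
polychlorinated formulas) where the most abundant isotopologue lies beyond
the window. The unit tests hold this implementation to an exhaustive
isotopologue-enumeration oracle at $10^{-6}$ relative abundance.

## Screening

Defaults follow the published acquisition and processing settings: scan
range m/z 100–2000, gradient 0–65 min, mass tolerance ±10 ppm with score
weight 0.60, isotope-ratio tolerance with weight 0.40, XIC width 0.02 Da
interpreted as the full window (±0.01 Da).

Two decisions were genuinely open:

* **Isotope tolerance dimension.** The source processing software describes
  the isotope-ratio tolerance "in ppm", which is dimensionally inconsistent
  for a ratio. Implemented as a relative fraction with default 0.10: the
  deviation is the mean over M+1 and M+2 of
  $|r_\text{obs}-r_\text{theo}| / \max(r_\text{theo}, 0.01)$, the floor
  preventing near-zero theoretical ratios from dominating. A feature with
  no recorded envelope scores 1.0 on the isotope component but carries a
  `no_envelope` flag.
* **Score shape and threshold.** Vendor score internals are unpublished;
  both components use the simplest monotone map, a linear ramp from 1 at
  zero deviation to 0 at tolerance, combined additively with the 60/40
  weights. The accept threshold defaults to 0.70 (a conventional vendor
  default) and is configurable. *Candidacy* is deliberately decoupled from
  the threshold: a compound counts as a screening candidate as soon as one
  of its adduct ions falls within the mass tolerance of one feature, which
  is the quantity the recovery guarantees below refer to; the threshold
  gates the reported match list. With Gaussian 3 ppm mass error the
  in-window probability is $P(|\varepsilon| < 10\,\text{ppm}) \approx
  0.9991$, so window-level recovery ≥ 99% is expected and observed, whereas
  any meaningful combined-score threshold would bite on envelope noise and
  make that guarantee unattainable.

Screening searches a m/z-sorted ion table by binary search, padded by one
tolerance-squared term so boundary ions (ppm measured against the
theoretical mass) are never clipped; equivalence with the brute-force
all-pairs scan is tested directly.

## MS/MS annotation

The neutral-loss vocabulary is fixed from the fragmentation chemistry of
the compound classes involved (water, CO, CO2, methyl radical, CH2O for
everything; butene side chain for phthalides; ketene, cross-ring 90/120 Da
cleavages, glucuronide and malonyl for flavonoids; benzoyl and
p-hydroxybenzoyl for monoterpene esters; caffeoyl/feruloyl for phenolic
acids; hexose/deoxyhexose/pentose residues universally) and is extensible
per call. Radical losses change electron parity; they are treated as plain
neutral mass subtractions, matching printed bracket arithmetic.

Explanation is exhaustive over loss multisets up to depth 3 (~1.3k
combinations for the full library — enumeration, not search heuristics).
Each observed peak takes the candidate with minimum absolute m/z error
within tolerance (10 ppm with a 2 mDa floor, since published fragment
tables deviate 1–9 ppm); ties break to the shorter path, then library
order, making annotation deterministic. Diagnostic retro-Diels–Alder ions
(negative 151.0032/135.0449, positive 153.0188/137.0244) are checked
directly for flavonoids and rank after equally-close single losses. Labels
report loss composition by mass class — `Xyl` means "a 132.0423 Da residue"
— and the engine follows mass even where published labels are inconsistent
(e.g. a printed "−Xyl" whose mass difference is 146 Da resolves to a
deoxyhexose loss and thereby flags the label).

Confidence grading: `standard_confirmed` requires a reference standard
whose retention time matches within 0.2 min *and* ≥ 1 explained fragment;
`tentative` requires ≥ 1 explained fragment; otherwise `candidate_only`.

## Prototype matching

Pooled post-dose plasma is treated as a single sample (the study design
pools the 0.5–3 h time points before analysis). A prototype call requires
an rt match (default ±0.2 min), a mass match (±10 ppm against the
formulation's found mass), ≥ 1 shared MS/MS fragment when the plasma
feature carries a spectrum (waived otherwise — IDA does not trigger on
every feature), and a dosed/blank intensity ratio ≥ 3 within the same
rt × m/z window (∞ when absent from blank). The blank criterion is this
module's construction: published workflows show blank-vs-dosed
chromatogram comparison without stating a rule, and a 3× enrichment with
full configurability is conventional practice. Isomer ties are handled by
matching every MS/MS-supported identification record and deduplicating
prototype calls per compound afterwards (most shared fragments, then
smallest mass deviation); without this, a compound identified against its
isomer's feature can carry the wrong retention time into the plasma match.

## Synthetic-data generator

The generator emulates the study design — formulation run, pooled
dosed-plasma run, blank run — with full ground truth:

* **Mass error**: observed m/z = theoretical × (1 + ε·10⁻⁶),
  ε ~ Normal(0, 3 ppm); the same law for MS/MS fragment m/z.
* **Isotope envelopes**: theoretical binned ratios × unbiased log-normal
  noise with CV 0.05.
* **Retention times**: uniform over 0–65 min with minimum spacing 0.1 min
  (sorted-uniform construction, capacity 651 compounds); packaged
  reference standards keep their curated retention times.
* **Adducts/polarity**: one adduct per compound; negative mode with
  probability 0.6, then [M−H]−/[M+Cl]−/[M+HCOO]− at 0.7/0.1/0.2 (positive
  analogues 0.7/0.2/0.1) — reflecting the predominance of deprotonated and
  formate ions in the curated table.
* **MS/MS**: up to 4 loss paths per compound, depth 1–3, sampled from the
  class-applicable vocabulary under the constraints that the cumulative
  loss composition fits inside the ion formula and the fragment stays in
  the m/z 100–2000 scan range; after 25 rejected draws the sampler falls
  back to the first feasible single loss, so any compound with a feasible
  fragmentation yields a spectrum. Each true fragment is omitted with
  dropout probability 0.1.
* **Absorption**: per-class Bernoulli with defaults equal to the absorbed
  fractions reported for each class in the reference plasma study
  (phenolic acids 13/17, flavonoids 21/25, phthalides 8/10, monoterpenes
  3/5, saponins 4/8, others 12/39, alkaloids and anthraquinones 0).
  Absorbed compounds are copied into plasma with the same retention time,
  fresh mass/intensity/envelope noise and fresh fragment dropout.
* **Decoys**: matrix features with m/z uniform on 100–2000, resampled until
  ≥ 20 ppm from every planted ion of the same polarity; blank plasma
  contains decoys only.
* **Intensities**: log-normal (σ = 1) around arbitrary per-sample medians;
  intensities only gate blank ratios, so the law is documented but
  uncalibrated.

Identical configuration (including the seed) reproduces the datasets
bit-for-bit, and the emitted CSV/MGF files byte-identically.

What passing the synthetic benchmarks shows: the pipeline's bookkeeping,
tolerance logic, fragment arithmetic and blank subtraction are correct
under the stated noise model. What it does not show: performance on real
chromatograms — the generator has no peak shapes, co-elution, adduct
multiplicity per compound, in-source fragmentation, ionization suppression
or real matrix chemistry, and its decoys are mass-uniform rather than
biologically structured. Headline biological counts from instrument data
(hundreds of candidates, dozens of prototypes) depend on the actual raw
runs and are not reproducible from synthetic data; the packaged table is a
curation target for the mass arithmetic, not a claim that the pipeline
re-derives it.

## Numerical conventions and degenerate inputs

ppm deviations are measured relative to the theoretical (not observed)
mass; the tolerance boundary is inclusive. Fine-structure peaks are merged
at $10^{-7}$ Da. Formulas with zero counts drop the element; the empty
formula has mass 0 and no isotope pattern. Features must lie inside the
scan range and gradient; violations raise rather than silently clip.
Reports order rows by retention time then m/z with 1-based numbering, print
m/z to 4 dp and ppm to 1 dp, and round-trip losslessly at that precision.
Unknown configuration keys are rejected; every effective tolerance, weight
and seed is logged.

## Problem sizes used by the test suite

The exhaustive isotope-oracle comparison covers all C/H/N/O formulas with
≤ 12 atoms (1,819) plus every one- and two-element formula over the full
ten-element alphabet; screening equivalence uses 200 ions × ~120 features;
the recovery benchmark plants 500 compounds from a 667-entry padded
database over 10 seeds (5,000 planted ions); end-to-end studies run on the
packaged 117-compound database with 100 decoys. These sizes keep the whole
suite under a minute on one CPU while leaving every statistical check
well-powered.
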