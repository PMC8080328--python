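"""Neutral-loss MS/MS annotation and identification confidence.

Natural-product MS/MS spectra are dominated by a small vocabulary of neutral
losses — water, CO, CO2, methyl radicals, sugar residues (hexose 162 Da,
deoxyhexose 146 Da, pentose 132 Da), acyl groups — plus, for flavonoids, the
diagnostic retro-Diels-Alder (RDA) A-/B-ring ions.  A fragment is explained
by breadth-first search over multisets of class-appropriate losses from the
precursor's theoretical m/z; each observed peak gets the minimum-|error|
explanation within tolerance.

Sugar names are mass-class aliases: MS cannot distinguish glucose from
galactose (both 162.0528) or xylose from arabinose (both 132.0423), so "Glc",
"Rha" and "Xyl" label the mass, not the stereochemistry.  Radical losses
(CH3) are treated as plain neutral mass subtractions, matching the bracket
arithmetic conventionally printed in annotation tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem import ElementCounts, monoisotopic_mass, parse_formula, ppm_error
from .database import CompoundRecord, TheoreticalIon
from .screening import CandidateMatch

__all__ = [
    "NeutralLoss",
    "DEFAULT_LOSSES",
    "DiagnosticIon",
    "RDA_IONS",
    "MSMSSpectrum",
    "FragmentAnnotation",
    "IdentificationRecord",
    "explain_fragments",
    "assign_confidence",
]

FRAGMENT_MZ_RANGE = (100.0, 2000.0)


@dataclass(frozen=True)
class NeutralLoss:
    name: str
    formula: tuple[tuple[str, int], ...]
    applicable_classes: frozenset[str] = frozenset()  # empty = universal

    @property
    def exact_mass(self) -> float:
        return monoisotopic_mass(dict(self.formula))

    def applies_to(self, compound_class: str) -> bool:
        return not self.applicable_classes or compound_class in self.applicable_classes


def _loss(name: str, formula: str, *classes: str) -> NeutralLoss:
    return NeutralLoss(
        name=name,
        formula=tuple(sorted(parse_formula(formula).items())),
        applicable_classes=frozenset(classes),
    )


#: the working neutral-loss vocabulary; order is the tie-break order
DEFAULT_LOSSES: tuple[NeutralLoss, ...] = (
    _loss("H2O", "H2O"),
    _loss("CO", "CO"),
    _loss("CO2", "CO2"),
    _loss("CH3", "CH3"),  # radical, 15.0235; parity ignored
    _loss("CH2O", "CH2O"),
    _loss("Glc", "C6H10O5"),  # hexose residue, 162.0528 (Glc = Gal)
    _loss("Rha", "C6H10O4"),  # deoxyhexose residue, 146.0579
    _loss("Xyl", "C5H8O4"),  # pentose residue, 132.0423 (Xyl = Arb)
    _loss("C4H8", "C4H8", "phthalide"),  # butyl side chain, 56.0626
    _loss("C2H2O", "C2H2O", "flavonoid"),  # ketene, 42.0106
    _loss("C3H6O3", "C3H6O3", "flavonoid"),  # cross-ring sugar cleavage, 90.0317
    _loss("C4H8O4", "C4H8O4", "flavonoid"),  # cross-ring sugar cleavage, 120.0423
    _loss("GlcA", "C6H8O6", "flavonoid"),  # glucuronide residue, 176.0321
    _loss("Bz", "C7H6O2", "monoterpene"),  # benzoic acid, 122.0368
    _loss("pHB", "C7H6O3", "monoterpene"),  # p-hydroxybenzoic acid, 138.0317
    _loss("Caffeoyl", "C9H6O3", "phenolic_acid"),  # 162.0317
    _loss("Feruloyl", "C10H8O3", "phenolic_acid"),  # 176.0473
    _loss("Malonyl", "C3H2O3", "flavonoid"),  # 86.0004
)


@dataclass(frozen=True)
class DiagnosticIon:
    """A class-diagnostic product ion observed at a fixed m/z."""

    name: str
    mz_pos: float | None
    mz_neg: float | None
    applicable_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mz_pos is None and self.mz_neg is None:
            raise ValueError("diagnostic ion needs at least one polarity m/z")

    def mz_for(self, polarity: str) -> float | None:
        return self.mz_pos if polarity == "positive" else self.mz_neg

    def applies_to(self, compound_class: str) -> bool:
        return not self.applicable_classes or compound_class in self.applicable_classes


#: flavonoid retro-Diels-Alder B-ring (1,3) cleavage products
RDA_IONS: tuple[DiagnosticIon, ...] = (
    DiagnosticIon("RDA_1,3A", 153.0188, 151.0032, frozenset({"flavonoid"})),
    DiagnosticIon("RDA_1,3B", 137.0244, 135.0449, frozenset({"flavonoid"})),
)


@dataclass(frozen=True)
class MSMSSpectrum:
    precursor_mz: float
    polarity: str
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity), sorted by mz
    spectrum_id: str | None = None

    def __post_init__(self) -> None:
        mzs = [m for m, _ in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("spectrum peaks must be sorted by m/z")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class FragmentAnnotation:
    observed_mz: float
    theoretical_mz: float
    error_ppm: float
    loss_path: tuple[NeutralLoss, ...] = ()
    diagnostic: DiagnosticIon | None = None

    def label(self, adduct_name: str) -> str:
        """Bracket notation, e.g. ``"[M-H-Xyl-Glc]-"`` or ``"[M-H-2Glc]-"``."""
        if self.diagnostic is not None:
            return self.diagnostic.name
        head, _, sign = adduct_name.rpartition("]")
        if not self.loss_path:
            return adduct_name
        # compress repeated losses in first-appearance order
        seen: dict[str, int] = {}
        for loss in self.loss_path:
            seen[loss.name] = seen.get(loss.name, 0) + 1
        parts = [f"{n if n > 1 else ''}{name}" for name, n in seen.items()]
        return f"{head}-" + "-".join(parts) + "]" + sign


@dataclass(frozen=True)
class IdentificationRecord:
    compound: CompoundRecord
    adduct_name: str
    rt: float
    found_mz: float
    ppm_dev: float
    annotations: tuple[FragmentAnnotation, ...]
    confidence: str  # standard_confirmed | tentative | candidate_only

    def __post_init__(self) -> None:
        if self.confidence not in ("standard_confirmed", "tentative", "candidate_only"):
            raise ValueError(f"bad confidence {self.confidence!r}")
        if self.confidence != "candidate_only" and not self.annotations:
            raise ValueError(f"{self.confidence} requires >= 1 annotated fragment")


def _loss_combinations(
    losses: Sequence[NeutralLoss], max_depth: int
) -> list[tuple[float, tuple[int, ...]]]:
    combos: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    masses = [l.exact_mass for l in losses]
    for depth in range(1, max_depth + 1):
        for idxs in itertools.combinations_with_replacement(range(len(losses)), depth):
            combos.append((sum(masses[i] for i in idxs), idxs))
    return combos


def explain_fragments(
    ion: TheoreticalIon,
    spectrum: MSMSSpectrum,
    losses: Sequence[NeutralLoss] | None = None,
    max_depth: int = 3,
    frag_tol_ppm: float = 10.0,
    frag_tol_floor_da: float = 0.002,
    diagnostics: Sequence[DiagnosticIon] = RDA_IONS,
) -> list[FragmentAnnotation]:
    """Assign each observed MS/MS peak its best neutral-loss explanation.

    Candidate fragment m/z values are the precursor's theoretical m/z minus
    every multiset of up to ``max_depth`` class-applicable losses, plus any
    class-diagnostic ions.  Each peak takes the candidate of minimum absolute
    error within tolerance (ppm with an absolute floor); ties break to the
    shorter loss path, then library order.  Unexplained peaks are omitted.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if spectrum.polarity != ion.adduct.polarity:
        raise ValueError("spectrum polarity does not match ion polarity")
    losses = tuple(DEFAULT_LOSSES if losses is None else losses)
    cls = ion.compound.compound_class
    applicable = [l for l in losses if l.applies_to(cls)]
    combos = _loss_combinations(applicable, max_depth)

    diag_candidates = [
        (d.mz_for(spectrum.polarity), d) for d in diagnostics if d.applies_to(cls)
    ]

    annotations = []
    for obs_mz, _intensity in spectrum.peaks:
        best = None  # (abs_err, path_len, path, annotation)
        for loss_mass, idxs in combos:
            theo = ion.mz - loss_mass / abs(ion.adduct.charge)
            if theo <= 0:
                continue
            err = obs_mz - theo
            tol = max(frag_tol_ppm * 1e-6 * theo, frag_tol_floor_da)
            if abs(err) > tol:
                continue
            key = (abs(err), len(idxs), idxs)
            if best is None or key < best[0]:
                ann = FragmentAnnotation(
                    observed_mz=obs_mz,
                    theoretical_mz=theo,
                    error_ppm=ppm_error(obs_mz, theo),
                    loss_path=tuple(applicable[i] for i in idxs),
                )
                best = (key, ann)
        for diag_mz, diag in diag_candidates:
            if diag_mz is None:
                continue
            err = obs_mz - diag_mz
            tol = max(frag_tol_ppm * 1e-6 * diag_mz, frag_tol_floor_da)
            if abs(err) > tol:
                continue
            # diagnostics rank after equally-close single-step losses
            key = (abs(err), 1, (len(losses) + 1,))
            if best is None or key < best[0]:
                ann = FragmentAnnotation(
                    observed_mz=obs_mz,
                    theoretical_mz=diag_mz,
                    error_ppm=ppm_error(obs_mz, diag_mz),
                    diagnostic=diag,
                )
                best = (key, ann)
        if best is not None:
            annotations.append(best[1])
    return annotations


def assign_confidence(
    candidate: CandidateMatch,
    annotations: Sequence[FragmentAnnotation],
    standards_rt_tol: float = 0.2,
) -> IdentificationRecord:
    """Grade a screened candidate into the three-level confidence scheme.

    ``standard_confirmed`` needs a reference standard whose retention time
    matches within ``standards_rt_tol`` minutes *and* at least one annotated
    fragment; ``tentative`` needs at least one annotated fragment; anything
    else stays ``candidate_only``.
    """
    compound = candidate.ion.compound
    annotations = tuple(annotations)
    if not annotations:
        confidence = "candidate_only"
    elif (
        compound.is_reference_standard
        and compound.reference_rt is not None
        and abs(candidate.feature.rt - compound.reference_rt) <= standards_rt_tol
    ):
        confidence = "standard_confirmed"
    else:
        confidence = "tentative"
    return IdentificationRecord(
        compound=compound,
        adduct_name=candidate.ion.adduct.name,
        rt=candidate.feature.rt,
        found_mz=candidate.feature.mz,
        ppm_dev=candidate.ppm_dev,
        annotations=annotations,
        confidence=confidence,
    )
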