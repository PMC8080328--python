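"""End-to-end orchestration: screen -> annotate -> match prototypes.

Mirrors the four-step workflow: expand the components database into
theoretical ions, screen MS1 features by accurate mass + isotope ratio,
explain MS/MS fragments by neutral losses, then re-find the identified
constituents in dosed plasma with blank subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .database import CompoundRecord, build_ion_table
from .fragments import (
    DEFAULT_LOSSES,
    IdentificationRecord,
    MSMSSpectrum,
    NeutralLoss,
    assign_confidence,
    explain_fragments,
)
from .plasma import PrototypeConfig, PrototypeRecord, match_prototypes
from .screening import CandidateMatch, Feature, ScreeningConfig, screen_features
from .simulate import (
    GroundTruth,
    RecoveryReport,
    SimulationConfig,
    SyntheticStudy,
    generate_dataset,
    recovery_report,
)

__all__ = [
    "AnnotationConfig",
    "StudyResult",
    "screen_both_polarities",
    "annotate_candidates",
    "best_identifications",
    "run_study",
]

_CONF_RANK = {"standard_confirmed": 2, "tentative": 1, "candidate_only": 0}


@dataclass(frozen=True)
class AnnotationConfig:
    frag_tol_ppm: float = 10.0
    frag_tol_floor_da: float = 0.002
    max_depth: int = 3
    standards_rt_tol: float = 0.2

    def __post_init__(self) -> None:
        if self.frag_tol_ppm <= 0 or self.max_depth < 1:
            raise ValueError("invalid annotation config")


def screen_both_polarities(
    records: Sequence[CompoundRecord],
    features: Sequence[Feature],
    cfg: ScreeningConfig | None = None,
):
    """Screen a mixed-polarity feature list against per-polarity ion tables."""
    cfg = cfg or ScreeningConfig()
    candidates: list[CandidateMatch] = []
    candidate_compounds: set[str] = set()
    for polarity in ("negative", "positive"):
        subset = [f for f in features if f.polarity == polarity]
        if not subset:
            continue
        table = build_ion_table(records, polarity)
        found, summary = screen_features(subset, table, cfg)
        candidates.extend(found)
        candidate_compounds |= summary.candidate_compounds
    return candidates, frozenset(candidate_compounds)


def annotate_candidates(
    candidates: Sequence[CandidateMatch],
    spectra: Mapping[str, MSMSSpectrum],
    cfg: AnnotationConfig | None = None,
    losses: Sequence[NeutralLoss] | None = None,
) -> list[IdentificationRecord]:
    """Explain each candidate's linked MS/MS spectrum and grade confidence."""
    cfg = cfg or AnnotationConfig()
    out = []
    for cand in candidates:
        ref = cand.feature.ms2_ref
        spectrum = spectra.get(ref) if ref else None
        annotations = []
        if spectrum is not None and spectrum.peaks:
            annotations = explain_fragments(
                cand.ion,
                spectrum,
                losses=losses,
                max_depth=cfg.max_depth,
                frag_tol_ppm=cfg.frag_tol_ppm,
                frag_tol_floor_da=cfg.frag_tol_floor_da,
            )
        out.append(assign_confidence(cand, annotations, cfg.standards_rt_tol))
    return out


def best_identifications(
    records: Sequence[IdentificationRecord],
) -> list[IdentificationRecord]:
    """One record per compound: highest confidence, then most annotations."""
    best: dict[str, IdentificationRecord] = {}
    for rec in records:
        cur = best.get(rec.compound.name)
        if cur is None or (
            (_CONF_RANK[rec.confidence], len(rec.annotations))
            > (_CONF_RANK[cur.confidence], len(cur.annotations))
        ):
            best[rec.compound.name] = rec
    return sorted(best.values(), key=lambda r: (r.rt, r.found_mz))


@dataclass(frozen=True)
class StudyResult:
    study: SyntheticStudy
    candidates: tuple[CandidateMatch, ...]
    identifications: tuple[IdentificationRecord, ...]  # deduped, MS/MS-supported
    prototypes: tuple[PrototypeRecord, ...]
    class_summary: dict[str, int]
    recovery: RecoveryReport


def run_study(
    records: Sequence[CompoundRecord],
    sim_cfg: SimulationConfig | None = None,
    screen_cfg: ScreeningConfig | None = None,
    annot_cfg: AnnotationConfig | None = None,
    proto_cfg: PrototypeConfig | None = None,
) -> StudyResult:
    """Simulate a study from ``records`` and run the full pipeline over it."""
    sim_cfg = sim_cfg or SimulationConfig()
    study = generate_dataset(records, sim_cfg)

    candidates, candidate_compounds = screen_both_polarities(
        records, study.formulation_features, screen_cfg
    )
    annotated = annotate_candidates(candidates, study.formulation_spectra, annot_cfg)
    confirmed = [r for r in annotated if r.confidence != "candidate_only"]
    identifications = best_identifications(confirmed)

    prototypes: list[PrototypeRecord] = []
    class_summary: dict[str, int] = {}
    if confirmed:
        # match against every MS/MS-supported record (isomer ties included),
        # not just the per-compound best: the isomer that carried the right
        # retention time may not be the deduplication winner
        prototypes, class_summary = match_prototypes(
            confirmed,
            study.plasma_features,
            study.plasma_spectra,
            study.blank_features,
            proto_cfg,
        )

    truth = study.truth
    recovery = recovery_report(
        truth,
        candidate_compounds=set(candidate_compounds),
        identified_compounds={r.compound.name for r in identifications},
        prototype_compounds={p.identification.compound.name for p in prototypes},
        accepted_decoy_ids={
            c.feature.feature_id for c in candidates if c.feature.feature_id
        },
    )
    return StudyResult(
        study=study,
        candidates=tuple(candidates),
        identifications=tuple(identifications),
        prototypes=tuple(prototypes),
        class_summary=class_summary,
        recovery=recovery,
    )
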