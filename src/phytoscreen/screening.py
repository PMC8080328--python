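"""MS1 candidate screening against the theoretical ion table.

A feature matches an ion when its m/z falls within the mass tolerance
(+-10 ppm by default); the match quality is a weighted combination of a mass
score (60%) and an isotope-ratio score (40%), each a linear ramp from 1 at
zero deviation to 0 at the tolerance.  Candidates below the combined-score
threshold are dropped.  XIC extraction uses a fixed-width m/z window
(0.02 Da full width by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import ppm_error
from .database import TheoreticalIon

__all__ = [
    "Feature",
    "MS1Scan",
    "ScreeningConfig",
    "CandidateMatch",
    "ScreeningSummary",
    "extract_xic",
    "score_candidate",
    "screen_features",
]

MZ_RANGE = (100.0, 2000.0)  # instrument full-scan range
RT_RANGE = (0.0, 65.0)  # chromatographic gradient, minutes


@dataclass(frozen=True)
class Feature:
    """One observed centroided MS1 entity."""

    rt: float
    mz: float
    polarity: str
    intensity: float
    isotope_envelope: tuple[tuple[int, float], ...] = ()
    ms2_ref: str | None = None
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if not MZ_RANGE[0] <= self.mz <= MZ_RANGE[1]:
            raise ValueError(f"feature m/z {self.mz} outside scan range {MZ_RANGE}")
        if not RT_RANGE[0] <= self.rt <= RT_RANGE[1]:
            raise ValueError(f"feature rt {self.rt} outside gradient {RT_RANGE}")
        if self.intensity <= 0:
            raise ValueError("feature intensity must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class MS1Scan:
    rt: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class ScreeningConfig:
    mass_tol_ppm: float = 10.0
    mass_weight: float = 0.60
    isotope_tol: float = 0.10  # relative ratio deviation, dimensionless
    isotope_weight: float = 0.40
    accept_threshold: float = 0.70
    xic_width_da: float = 0.02  # full window width
    isotope_ratio_floor: float = 0.01  # denominators below this are clamped

    def __post_init__(self) -> None:
        if abs(self.mass_weight + self.isotope_weight - 1.0) > 1e-9:
            raise ValueError("score weights must sum to 1.0")
        if self.mass_tol_ppm <= 0 or self.isotope_tol <= 0 or self.xic_width_da <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 <= self.accept_threshold <= 1.0:
            raise ValueError("accept_threshold must be in [0, 1]")


@dataclass(frozen=True)
class CandidateMatch:
    feature: Feature
    ion: TheoreticalIon
    ppm_dev: float
    isotope_dev: float | None  # None when the feature carries no envelope
    mass_score: float
    isotope_score: float
    combined_score: float

    @property
    def no_envelope(self) -> bool:
        return self.isotope_dev is None


@dataclass
class ScreeningSummary:
    """Counts from one screening pass.

    A compound is a *candidate* as soon as one of its adduct ions falls
    within the mass tolerance of one feature; the combined-score threshold
    additionally gates which matches are reported.  Both the unique-compound
    and the compound x adduct counting of candidates are kept, since a
    screening hit list can be tallied either way.
    """

    n_features: int = 0
    n_scored: int = 0  # window matches, before the score threshold
    n_accepted: int = 0
    n_unique_compounds: int = 0
    n_compound_adduct_pairs: int = 0
    candidate_compounds: frozenset[str] = frozenset()
    accepted_compounds: frozenset[str] = frozenset()


def extract_xic(
    scans: Sequence[MS1Scan], target_mz: float, width_da: float = 0.02
) -> list[tuple[float, float]]:
    """Summed centroid intensity per scan within |mz - target| <= width/2."""
    if width_da <= 0:
        raise ValueError("XIC width must be positive")
    half = width_da / 2.0
    out = []
    for scan in scans:
        mask = np.abs(np.asarray(scan.mz) - target_mz) <= half
        out.append((scan.rt, float(np.sum(np.asarray(scan.intensity)[mask]))))
    return out


def score_candidate(
    feature: Feature, ion: TheoreticalIon, cfg: ScreeningConfig | None = None
) -> CandidateMatch | None:
    """Score one feature against one theoretical ion; None if out of tolerance."""
    cfg = cfg or ScreeningConfig()
    if feature.polarity != ion.adduct.polarity:
        raise ValueError(
            f"polarity mismatch: feature {feature.polarity}, ion {ion.adduct.polarity}"
        )
    dev = ppm_error(feature.mz, ion.mz)
    if abs(dev) > cfg.mass_tol_ppm:
        return None
    mass_score = 1.0 - abs(dev) / cfg.mass_tol_ppm

    theo = ion.pattern.binned_ratios()
    iso_dev: float | None = None
    if feature.isotope_envelope:
        obs = dict(feature.isotope_envelope)
        offsets = sorted(k for k in theo if k >= 1)
        devs = []
        for k in offsets:
            t = theo[k]
            o = obs.get(k, 0.0)
            devs.append(abs(o - t) / max(t, cfg.isotope_ratio_floor))
        iso_dev = float(np.mean(devs)) if devs else 0.0
        isotope_score = max(0.0, 1.0 - iso_dev / cfg.isotope_tol)
    else:
        # no envelope observed: neutral isotope evidence, flagged via no_envelope
        isotope_score = 1.0
    combined = cfg.mass_weight * mass_score + cfg.isotope_weight * isotope_score
    return CandidateMatch(
        feature=feature,
        ion=ion,
        ppm_dev=dev,
        isotope_dev=iso_dev,
        mass_score=mass_score,
        isotope_score=isotope_score,
        combined_score=combined,
    )


def screen_features(
    features: Sequence[Feature],
    ion_table: Sequence[TheoreticalIon],
    cfg: ScreeningConfig | None = None,
) -> tuple[list[CandidateMatch], ScreeningSummary]:
    """Match every feature against all in-tolerance ions of the sorted table.

    Returns accepted candidates (combined score >= threshold) and a summary
    counting both unique candidate compounds and compound x adduct pairs —
    the two ways of counting a "screened candidate".
    """
    cfg = cfg or ScreeningConfig()
    mzs = np.array([ion.mz for ion in ion_table])
    if np.any(np.diff(mzs) < 0):
        raise ValueError("ion table must be sorted by m/z")
    scored: list[CandidateMatch] = []
    for feature in features:
        # ppm is taken relative to the theoretical m/z; pad the window so the
        # binary search never clips an exactly-at-tolerance ion above the feature
        tol_da = feature.mz * cfg.mass_tol_ppm * 1e-6 * (1.0 + 2e-6 * cfg.mass_tol_ppm)
        lo = int(np.searchsorted(mzs, feature.mz - tol_da, side="left"))
        hi = int(np.searchsorted(mzs, feature.mz + tol_da, side="right"))
        for ion in ion_table[lo:hi]:
            if ion.adduct.polarity != feature.polarity:
                continue
            match = score_candidate(feature, ion, cfg)
            if match is not None:
                scored.append(match)
    accepted = [m for m in scored if m.combined_score >= cfg.accept_threshold]
    compounds = {m.ion.compound.name for m in scored}
    pairs = {(m.ion.compound.name, m.ion.adduct.name) for m in scored}
    summary = ScreeningSummary(
        n_features=len(features),
        n_scored=len(scored),
        n_accepted=len(accepted),
        n_unique_compounds=len(compounds),
        n_compound_adduct_pairs=len(pairs),
        candidate_compounds=frozenset(compounds),
        accepted_compounds=frozenset(m.ion.compound.name for m in accepted),
    )
    return accepted, summary
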