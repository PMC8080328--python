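"""Serum-pharmacochemistry prototype matching.

An absorbed prototype is a formulation constituent re-found, unmetabolized,
in post-dose plasma: a dosed-plasma feature must match a formulation
identification on retention time and accurate mass, share MS/MS fragments
with it when a plasma spectrum exists, and be absent from (or strongly
enriched over) blank plasma.  Plasma from the sampling time points is pooled
before analysis, so a single dosed sample is matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fragments import IdentificationRecord, MSMSSpectrum
from .screening import Feature

__all__ = ["PrototypeConfig", "PrototypeRecord", "match_prototypes"]


@dataclass(frozen=True)
class PrototypeConfig:
    rt_tol_min: float = 0.2
    mass_tol_ppm: float = 10.0
    min_shared_fragments: int = 1
    blank_ratio_min: float = 3.0
    frag_tol_ppm: float = 10.0
    frag_tol_floor_da: float = 0.002

    def __post_init__(self) -> None:
        if self.rt_tol_min <= 0 or self.mass_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.blank_ratio_min < 1:
            raise ValueError("blank_ratio_min must be >= 1")


@dataclass(frozen=True)
class PrototypeRecord:
    identification: IdentificationRecord
    plasma_feature: Feature
    rt_delta: float
    ppm_dev: float
    n_shared_fragments: int
    blank_ratio: float  # dosed/blank intensity; inf when absent from blank


def _shared_fragments(
    identification: IdentificationRecord,
    spectrum: MSMSSpectrum,
    cfg: PrototypeConfig,
) -> int:
    """Count formulation-annotated fragments re-observed in the plasma spectrum."""
    shared = 0
    for ann in identification.annotations:
        tol = max(cfg.frag_tol_ppm * 1e-6 * ann.theoretical_mz, cfg.frag_tol_floor_da)
        if any(abs(mz - ann.theoretical_mz) <= tol for mz, _ in spectrum.peaks):
            shared += 1
    return shared


def match_prototypes(
    identifications: Sequence[IdentificationRecord],
    plasma_features: Sequence[Feature],
    plasma_spectra: Mapping[str, MSMSSpectrum] | None = None,
    blank_features: Sequence[Feature] = (),
    cfg: PrototypeConfig | None = None,
) -> tuple[list[PrototypeRecord], dict[str, int]]:
    """Call absorbed prototypes and summarise them per compound class.

    For each formulation identification the best dosed-plasma feature within
    ``rt_tol_min`` and ``mass_tol_ppm`` is taken; the fragment-sharing
    requirement is waived when that feature carries no MS/MS spectrum.  The
    blank criterion compares the dosed intensity with the most intense blank
    feature in the same rt x m/z window.
    """
    if not identifications:
        raise ValueError("empty identification list")
    cfg = cfg or PrototypeConfig()
    plasma_spectra = plasma_spectra or {}

    records: list[PrototypeRecord] = []
    for ident in identifications:
        best: tuple[float, Feature] | None = None
        for feat in plasma_features:
            if abs(feat.rt - ident.rt) > cfg.rt_tol_min:
                continue
            dev = (feat.mz - ident.found_mz) / ident.found_mz * 1e6
            if abs(dev) > cfg.mass_tol_ppm:
                continue
            key = abs(dev)
            if best is None or key < best[0]:
                best = (key, feat)
        if best is None:
            continue
        feat = best[1]
        ppm_dev = (feat.mz - ident.found_mz) / ident.found_mz * 1e6

        spectrum = plasma_spectra.get(feat.ms2_ref) if feat.ms2_ref else None
        if spectrum is not None:
            n_shared = _shared_fragments(ident, spectrum, cfg)
            if n_shared < cfg.min_shared_fragments:
                continue
        else:
            n_shared = 0  # requirement waived: no plasma MS/MS acquired

        blank_max = 0.0
        for bf in blank_features:
            if (
                abs(bf.rt - feat.rt) <= cfg.rt_tol_min
                and abs(bf.mz - feat.mz) / feat.mz * 1e6 <= cfg.mass_tol_ppm
            ):
                blank_max = max(blank_max, bf.intensity)
        ratio = math.inf if blank_max == 0 else feat.intensity / blank_max
        if ratio < cfg.blank_ratio_min:
            continue

        records.append(
            PrototypeRecord(
                identification=ident,
                plasma_feature=feat,
                rt_delta=feat.rt - ident.rt,
                ppm_dev=ppm_dev,
                n_shared_fragments=n_shared,
                blank_ratio=ratio,
            )
        )

    # several identification records of one compound (isomer ties) may each
    # find a plasma match; keep the best-supported call per compound
    best_per_compound: dict[str, PrototypeRecord] = {}
    for rec in records:
        name = rec.identification.compound.name
        cur = best_per_compound.get(name)
        if cur is None or (rec.n_shared_fragments, -abs(rec.ppm_dev)) > (
            cur.n_shared_fragments,
            -abs(cur.ppm_dev),
        ):
            best_per_compound[name] = rec
    records = sorted(
        best_per_compound.values(),
        key=lambda r: (r.identification.rt, r.identification.found_mz),
    )

    summary: dict[str, int] = {}
    for rec in records:
        cls = rec.identification.compound.compound_class
        summary[cls] = summary.get(cls, 0) + 1
    return records, summary
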