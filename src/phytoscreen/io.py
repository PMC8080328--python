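"""File formats and configuration.

Canonical interchange dialects: MGF for MS/MS spectra (PEPMASS required,
CHARGE sign carries the polarity), CSV for feature tables and reports, YAML
for pipeline configuration.  Every report can be re-read into its domain
types at the stated precision (m/z 4 dp, ppm 1 dp).  Vendor raw formats are
out of scope; instrument settings ride along as inert config metadata.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .fragments import IdentificationRecord, MSMSSpectrum
from .pipeline import AnnotationConfig
from .plasma import PrototypeConfig, PrototypeRecord
from .screening import Feature, ScreeningConfig
from .simulate import SimulationConfig

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "write_identification_report",
    "read_identification_report",
    "write_prototype_report",
    "PipelineConfig",
    "load_config",
]

logger = logging.getLogger("phytoscreen")

FEATURE_COLUMNS = [
    "feature_id",
    "rt_min",
    "mz",
    "polarity",
    "intensity",
    "iso1_ratio",
    "iso2_ratio",
    "ms2_id",
]


def read_mgf(source) -> list[MSMSSpectrum]:
    """Read an MGF file into spectra; peaks are sorted on read.

    Blocks without PEPMASS or CHARGE are skipped with a logged warning.
    """
    spectra = []
    with _mgf.MGF(str(source), convert_arrays=1) as reader:
        for block in reader:
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            charge = params.get("charge")
            title = params.get("title")
            if not pepmass or pepmass[0] is None:
                logger.warning("skipping MGF block %r without PEPMASS", title)
                continue
            if not charge:
                logger.warning("skipping MGF block %r without CHARGE", title)
                continue
            polarity = "negative" if int(charge[0]) < 0 else "positive"
            peaks = sorted(
                zip(block["m/z array"].tolist(), block["intensity array"].tolist())
            )
            spectra.append(
                MSMSSpectrum(
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    peaks=tuple(peaks),
                    spectrum_id=str(title) if title is not None else None,
                )
            )
    if not spectra:
        logger.warning("no spectra read from %s", source)
    return spectra


def write_mgf(spectra: Sequence[MSMSSpectrum], path) -> None:
    """Write spectra as MGF, m/z to 6 dp round-trip precision."""
    entries = []
    for i, spec in enumerate(spectra):
        mzs = np.array([m for m, _ in spec.peaks])
        ints = np.array([x for _, x in spec.peaks])
        entries.append(
            {
                "m/z array": mzs,
                "intensity array": ints,
                "params": {
                    "title": spec.spectrum_id or f"spectrum_{i}",
                    "pepmass": spec.precursor_mz,
                    "charge": "1-" if spec.polarity == "negative" else "1+",
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


def write_feature_table(features: Sequence[Feature], path) -> None:
    rows = []
    for f in features:
        env = dict(f.isotope_envelope)
        rows.append(
            {
                "feature_id": f.feature_id,
                "rt_min": f.rt,
                "mz": f.mz,
                "polarity": f.polarity,
                "intensity": f.intensity,
                "iso1_ratio": env.get(1, np.nan),
                "iso2_ratio": env.get(2, np.nan),
                "ms2_id": f.ms2_ref,
            }
        )
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_table(path) -> list[Feature]:
    df = pd.read_csv(path)
    missing = {"rt_min", "mz", "polarity", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    features = []
    for _, row in df.iterrows():
        envelope = []
        for k, col in ((1, "iso1_ratio"), (2, "iso2_ratio")):
            if col in df.columns and pd.notna(row[col]):
                envelope.append((k, float(row[col])))
        features.append(
            Feature(
                rt=float(row["rt_min"]),
                mz=float(row["mz"]),
                polarity=str(row["polarity"]),
                intensity=float(row["intensity"]),
                isotope_envelope=tuple(envelope),
                ms2_ref=(
                    str(row["ms2_id"])
                    if "ms2_id" in df.columns and pd.notna(row["ms2_id"])
                    else None
                ),
                feature_id=(
                    str(row["feature_id"])
                    if "feature_id" in df.columns and pd.notna(row["feature_id"])
                    else None
                ),
            )
        )
    return features


REPORT_COLUMNS = [
    "no",
    "rt_min",
    "adduct",
    "theoretical_mz",
    "found_mz",
    "ppm",
    "formula",
    "name",
    "fragments",
    "sources",
    "confidence",
    "prototype",
]


def write_identification_report(
    records: Sequence[IdentificationRecord],
    path,
    prototypes: set[str] | None = None,
) -> pd.DataFrame:
    """Identification table: ordered by rt then m/z, 1-based numbering,
    fragment annotations in bracket notation (e.g. ``721.4158 [M-H-Xyl]-``)."""
    from .chem import adduct_mz, get_adduct

    prototypes = prototypes or set()
    ordered = sorted(records, key=lambda r: (r.rt, r.found_mz))
    rows = []
    for i, rec in enumerate(ordered, start=1):
        theo = adduct_mz(rec.compound.counts, get_adduct(rec.adduct_name))
        frags = ", ".join(
            f"{a.observed_mz:.4f} {a.label(rec.adduct_name)}" for a in rec.annotations
        )
        rows.append(
            {
                "no": i,
                "rt_min": round(rec.rt, 2),
                "adduct": rec.adduct_name,
                "theoretical_mz": f"{theo:.4f}",
                "found_mz": f"{rec.found_mz:.4f}",
                "ppm": f"{rec.ppm_dev:.1f}",
                "formula": rec.compound.formula_str,
                "name": rec.compound.name,
                "fragments": frags,
                "sources": ";".join(sorted(rec.compound.sources)),
                "confidence": rec.confidence,
                "prototype": "P" if rec.compound.name in prototypes else "",
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_identification_report(path) -> pd.DataFrame:
    """Re-read a report preserving printed precision (masses as strings)."""
    return pd.read_csv(
        path,
        dtype={"theoretical_mz": str, "found_mz": str, "ppm": str},
        keep_default_na=False,
    )


def write_prototype_report(records: Sequence[PrototypeRecord], path) -> pd.DataFrame:
    rows = []
    ordered = sorted(records, key=lambda r: (r.identification.rt, r.identification.found_mz))
    for i, rec in enumerate(ordered, start=1):
        ident = rec.identification
        rows.append(
            {
                "no": i,
                "name": ident.compound.name,
                "formula": ident.compound.formula_str,
                "compound_class": ident.compound.compound_class,
                "adduct": ident.adduct_name,
                "rt_min": round(ident.rt, 2),
                "plasma_rt_min": round(ident.rt + rec.rt_delta, 2),
                "plasma_mz": f"{rec.plasma_feature.mz:.4f}",
                "ppm_dev": f"{rec.ppm_dev:.1f}",
                "n_shared_fragments": rec.n_shared_fragments,
                "blank_ratio": "inf" if rec.blank_ratio == float("inf") else f"{rec.blank_ratio:.1f}",
                "prototype": "P",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "no",
            "name",
            "formula",
            "compound_class",
            "adduct",
            "rt_min",
            "plasma_rt_min",
            "plasma_mz",
            "ppm_dev",
            "n_shared_fragments",
            "blank_ratio",
            "prototype",
        ],
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for the whole workflow.

    ``instrument`` is inert metadata (source voltages, gas settings...) that
    is logged and echoed into reports but never computed on.
    """

    seed: int = 0
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    prototype: PrototypeConfig = field(default_factory=PrototypeConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    paths: dict = field(default_factory=dict)
    instrument: dict = field(default_factory=dict)


def _build(cls, data: Mapping, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    converted = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        converted[key] = value
    return cls(**converted)


def load_config(path) -> PipelineConfig:
    """Parse a YAML config file; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in (
        ("screening", ScreeningConfig),
        ("annotation", AnnotationConfig),
        ("prototype", PrototypeConfig),
        ("simulation", SimulationConfig),
    ):
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    for name in ("seed", "paths", "instrument"):
        if name in raw:
            kwargs[name] = raw[name]
    cfg = PipelineConfig(**kwargs)
    log_effective_config(cfg)
    return cfg


def log_effective_config(cfg: PipelineConfig) -> None:
    """Record every effective tolerance/weight/seed for auditability."""
    logger.info("seed=%d", cfg.seed)
    for section in ("screening", "annotation", "prototype", "simulation"):
        for key, value in asdict(getattr(cfg, section)).items():
            logger.info("%s.%s=%r", section, key, value)
    if cfg.instrument:
        logger.info("instrument metadata: %r", cfg.instrument)
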