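"""The self-built components database and its expansion into theoretical ions.

The search space of the whole workflow is a literature-derived table of
(compound name, molecular formula, source herbs) for each herb in the
formulation.  Loading merges duplicate compounds listed under several herbs,
normalises herb-code spellings, and skips unparseable rows with a report.
``build_ion_table`` expands the records into one entry per compound x adduct
with exact m/z and isotope pattern, sorted for binary search.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    ADDUCTS,
    Adduct,
    ElementCounts,
    IsotopePattern,
    adduct_mz,
    format_formula,
    get_adduct,
    isotope_pattern,
    parse_formula,
)

__all__ = [
    "COMPOUND_CLASSES",
    "HERB_CODES",
    "HERB_ALIASES",
    "CompoundRecord",
    "TheoreticalIon",
    "LoadReport",
    "load_database",
    "load_bundled_database",
    "load_bundled_table",
    "build_ion_table",
]

COMPOUND_CLASSES = frozenset(
    {
        "phenolic_acid",
        "flavonoid",
        "alkaloid",
        "phthalide",
        "monoterpene",
        "triterpenoid_saponin",
        "anthraquinone",
        "other",
    }
)

#: canonical herb codes for the twelve constituent medicinal herbs
HERB_CODES = frozenset(
    {"RG", "AS", "PL", "PO", "OJ", "CM", "LC", "AA", "CR", "CS", "LF", "BR"}
)

#: spelling variants seen in the literature (Latin vs pinyin derivations)
HERB_ALIASES = {"RP": "PL", "CO": "CS", "LB": "LF", "BC": "BR"}


def normalize_herb_code(code: str) -> str:
    code = code.strip().upper()
    code = HERB_ALIASES.get(code, code)
    if code not in HERB_CODES:
        raise ValueError(f"unknown herb code {code!r}")
    return code


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: tuple[tuple[str, int], ...]  # immutable ElementCounts items
    sources: frozenset[str]
    compound_class: str = "other"
    is_reference_standard: bool = False
    reference_rt: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if not self.sources:
            raise ValueError(f"{self.name}: sources must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"{self.name}: unknown class {self.compound_class!r}")
        if self.reference_rt is not None and not self.is_reference_standard:
            raise ValueError(f"{self.name}: reference_rt requires a reference standard")

    @property
    def counts(self) -> ElementCounts:
        return dict(self.formula)

    @property
    def formula_str(self) -> str:
        return format_formula(self.counts)


@dataclass(frozen=True)
class TheoreticalIon:
    """One compound x adduct screening reference."""

    compound: CompoundRecord
    adduct: Adduct
    mz: float
    pattern: IsotopePattern

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("ion m/z must be positive")


@dataclass
class LoadReport:
    n_rows: int = 0
    n_records: int = 0
    n_skipped: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)


_DEFAULT_COLUMNS = {
    "name": "name",
    "formula": "formula",
    "sources": "sources",
    "compound_class": "compound_class",
    "is_standard": "is_standard",
    "reference_rt": "reference_rt",
}


def load_database(
    table,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[CompoundRecord], LoadReport]:
    """Read a components database from CSV/TSV.

    ``table`` may be a path or an open text stream.  ``column_map`` maps the
    logical fields (name, formula, sources, and optionally compound_class,
    is_standard, reference_rt) to the file's column headers.  Rows whose
    formula does not parse, or whose herb codes are unknown, are skipped and
    counted.  Duplicate (name, formula) rows merge their source sets.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(table, sep=sep, engine="python" if sep is None else "c")
    for key in ("name", "formula", "sources"):
        if cols[key] not in df.columns:
            raise ValueError(f"mandatory column {cols[key]!r} missing from header")

    report = LoadReport(n_rows=len(df))
    merged: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        try:
            name = str(row[cols["name"]]).strip()
            counts = parse_formula(str(row[cols["formula"]]))
            raw_sources = str(row[cols["sources"]])
            sources = frozenset(
                normalize_herb_code(c)
                for c in raw_sources.replace(",", ";").split(";")
                if c.strip()
            )
            if not name or not sources:
                raise ValueError("empty name or sources")
            cls = "other"
            if cols["compound_class"] in df.columns:
                val = row[cols["compound_class"]]
                if pd.notna(val) and str(val).strip():
                    cls = str(val).strip()
            std = False
            if cols["is_standard"] in df.columns:
                std = str(row[cols["is_standard"]]).strip().lower() in ("true", "1", "yes")
            rt = None
            if std and cols["reference_rt"] in df.columns:
                val = row[cols["reference_rt"]]
                if pd.notna(val):
                    rt = float(val)
            key = (name, format_formula(counts))
            if key in merged:
                merged[key]["sources"] |= sources
                merged[key]["is_standard"] = merged[key]["is_standard"] or std
                if rt is not None and merged[key]["rt"] is None:
                    merged[key]["rt"] = rt
            else:
                merged[key] = dict(
                    counts=counts, sources=set(sources), cls=cls, is_standard=std, rt=rt
                )
                order.append(key)
        except (ValueError, KeyError) as exc:
            report.n_skipped += 1
            report.skipped.append((int(idx), str(exc)))

    records = [
        CompoundRecord(
            name=key[0],
            formula=tuple(sorted(merged[key]["counts"].items())),
            sources=frozenset(merged[key]["sources"]),
            compound_class=merged[key]["cls"],
            is_reference_standard=merged[key]["is_standard"],
            reference_rt=merged[key]["rt"],
        )
        for key in order
    ]
    report.n_records = len(records)
    if not records:
        raise ValueError("no valid rows in components database")
    return records, report


def _bundled_stream() -> _io.StringIO:
    data = (
        resources.files("phytoscreen")
        .joinpath("data/ygmm_identifications.csv")
        .read_text(encoding="utf-8")
    )
    return _io.StringIO(data)


def load_bundled_table() -> pd.DataFrame:
    """The packaged curated identification table for the YGMM formulation.

    117 constituents with printed adduct, theoretical and found m/z, signed
    ppm error, MS/MS fragment labels, source herbs, reference-standard and
    plasma-prototype flags.  Masses are kept as strings to preserve the
    printed precision.
    """
    return pd.read_csv(
        _bundled_stream(), dtype={"precursor_mz": str, "found_mz": str, "ppm": str}
    )


def load_bundled_database() -> tuple[list[CompoundRecord], LoadReport]:
    """Load the packaged table as a components database (117 records)."""
    return load_database(
        _bundled_stream(),
        column_map={"reference_rt": "rt_min"},
    )


def build_ion_table(
    records: Sequence[CompoundRecord],
    polarity: str,
    adducts: Iterable[Adduct | str] | None = None,
    prune_threshold: float = 1e-5,
    max_bins: int = 3,
) -> list[TheoreticalIon]:
    """Expand records into |records| x |adducts| theoretical ions, mz-sorted.

    The isotope pattern is computed for the *ion* formula (molecule plus
    adduct atoms), since that is what the instrument observes.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    if adducts is None:
        chosen = [a for a in ADDUCTS.values() if a.polarity == polarity]
    else:
        chosen = [get_adduct(a) for a in adducts]
    if not chosen:
        raise ValueError("adduct set must be non-empty")
    if any(a.polarity != polarity for a in chosen):
        raise ValueError("all adducts must match the requested polarity")

    ions = []
    pattern_cache: dict[str, IsotopePattern] = {}
    for rec in records:
        counts = rec.counts
        for adduct in chosen:
            ion_counts = adduct.ion_counts(counts)
            key = format_formula(ion_counts)
            pat = pattern_cache.get(key)
            if pat is None:
                pat = isotope_pattern(ion_counts, prune_threshold, max_bins)
                pattern_cache[key] = pat
            ions.append(
                TheoreticalIon(
                    compound=rec, adduct=adduct, mz=adduct_mz(counts, adduct), pattern=pat
                )
            )
    ions.sort(key=lambda i: i.mz)
    return ions
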