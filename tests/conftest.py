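from __future__ import annotations

import pytest

from phytoscreen.chem import ADDUCTS, adduct_mz, isotope_pattern, parse_formula
from phytoscreen.database import (
    CompoundRecord,
    TheoreticalIon,
    load_bundled_database,
    load_bundled_table,
)
from phytoscreen.screening import Feature


@pytest.fixture(scope="session")
def bundled_records():
    records, report = load_bundled_database()
    assert report.n_skipped == 0
    return records


@pytest.fixture(scope="session")
def bundled_table():
    return load_bundled_table()


def make_record(
    formula: str,
    name: str = "compound",
    compound_class: str = "other",
    sources=("LC",),
    is_standard: bool = False,
    reference_rt: float | None = None,
) -> CompoundRecord:
    return CompoundRecord(
        name=name,
        formula=tuple(sorted(parse_formula(formula).items())),
        sources=frozenset(sources),
        compound_class=compound_class,
        is_reference_standard=is_standard,
        reference_rt=reference_rt,
    )


def make_ion(formula: str, adduct: str, **record_kwargs) -> TheoreticalIon:
    rec = make_record(formula, **record_kwargs)
    add = ADDUCTS[adduct]
    return TheoreticalIon(
        compound=rec,
        adduct=add,
        mz=adduct_mz(rec.counts, add),
        pattern=isotope_pattern(add.ion_counts(rec.counts)),
    )


def make_feature(mz: float, polarity: str = "negative", rt: float = 10.0, **kwargs) -> Feature:
    kwargs.setdefault("intensity", 1e5)
    return Feature(rt=rt, mz=mz, polarity=polarity, **kwargs)
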