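"""Exact-mass chemistry kernel.

Molecular formulas are plain ``{element: count}`` dicts (Hill-style strings on
disk), masses are monoisotopic, and ion m/z values are electron-aware: forming
``[M+H]+`` adds a hydrogen atom *and removes an electron*, so the proton mass
(1.00727646 Da) rather than the hydrogen atom mass enters the arithmetic.  On
a high-resolution instrument the ~0.55 mDa electron term is well above the
mass accuracy at low m/z, and printed reference values only reproduce when it
is included.
"""

from __future__ import annotations

import functools
import itertools
import re
from dataclasses import dataclass, field

from .elements import ELECTRON_MASS, ISOTOPES, MONOISOTOPIC

__all__ = [
    "ElementCounts",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "Adduct",
    "ADDUCTS",
    "adduct_mz",
    "ppm_error",
    "IsotopePattern",
    "isotope_pattern",
]

#: a molecular formula: element symbol -> positive atom count
ElementCounts = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style formula string such as ``"C18H19NO5"``.

    Counts default to 1; repeated symbols accumulate.  Only elements with
    tabulated isotope data are accepted.  Isotope labels, charges and
    parenthesised groups are not part of the dialect.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: ElementCounts = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ISOTOPES:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n > 0:
            counts[symbol] = counts.get(symbol, 0) + n
        pos += len(symbol) + len(digits)
    return counts


def format_formula(counts: ElementCounts) -> str:
    """Canonical Hill-order writer: C, H, then other elements alphabetically."""
    parts = []
    order = [el for el in ("C", "H") if el in counts]
    order += sorted(el for el in counts if el not in ("C", "H"))
    for el in order:
        n = counts[el]
        if n < 0:
            raise ValueError(f"negative count for {el}")
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Sum of count x lightest-isotope exact mass, in Da."""
    try:
        return sum(MONOISOTOPIC[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class Adduct:
    """An ESI ion form: the atoms gained/lost and the charge they carry.

    ``delta`` holds signed atom counts relative to the neutral molecule
    (e.g. ``{"H": -1}`` for ``[M-H]-``), ``electron_delta`` the electrons
    gained (+) or lost (-) forming the ion.
    """

    name: str
    delta: tuple[tuple[str, int], ...]
    charge: int
    electron_delta: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        # a singly charged anion has gained one electron, a cation lost one
        if (self.charge > 0) != (self.electron_delta < 0):
            raise ValueError(f"{self.name}: electron_delta inconsistent with charge")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    def ion_counts(self, counts: ElementCounts) -> ElementCounts:
        """Element counts of the whole ion (molecule plus adduct atoms)."""
        ion = dict(counts)
        for el, n in self.delta:
            ion[el] = ion.get(el, 0) + n
            if ion[el] < 0:
                raise ValueError(
                    f"{self.name} removes {el} not present in {format_formula(counts)}"
                )
            if ion[el] == 0:
                del ion[el]
        if not ion:
            raise ValueError("resulting ion has no atoms")
        return ion


ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in (
        Adduct("[M+H]+", (("H", 1),), +1, -1),
        Adduct("[M+Na]+", (("Na", 1),), +1, -1),
        Adduct("[M+K]+", (("K", 1),), +1, -1),
        Adduct("[M-H]-", (("H", -1),), -1, +1),
        Adduct("[M+Cl]-", (("Cl", 1),), -1, +1),
        Adduct("[M+HCOO]-", (("C", 1), ("H", 1), ("O", 2)), -1, +1),
    )
}

POSITIVE_ADDUCTS = tuple(a for a in ADDUCTS.values() if a.charge > 0)
NEGATIVE_ADDUCTS = tuple(a for a in ADDUCTS.values() if a.charge < 0)

_ADDUCT_ALIASES = {
    "[M−H]−": "[M-H]-",  # unicode minus variants seen in the wild
    "[M+H]^+": "[M+H]+",
}


def get_adduct(name: str | Adduct) -> Adduct:
    if isinstance(name, Adduct):
        return name
    key = name.replace("−", "-").replace("^", "").replace(" ", "")
    key = _ADDUCT_ALIASES.get(key, key)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(f"unregistered adduct {name!r}") from None


def adduct_mz(counts: ElementCounts, adduct: str | Adduct) -> float:
    """Theoretical m/z of the adduct ion of a neutral molecule."""
    adduct = get_adduct(adduct)
    adduct.ion_counts(counts)  # validates the ion exists
    mass = monoisotopic_mass(counts)
    mass += sum(MONOISOTOPIC[el] * n for el, n in adduct.delta)
    mass += adduct.electron_delta * ELECTRON_MASS
    return mass / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class IsotopePattern:
    """Fine-structure isotopologue peaks and their nominal-offset binning.

    ``peaks`` are (mass, abundance-relative-to-base-peak) with strictly
    increasing masses; ``binned`` sums fine peaks into nominal offsets
    0..max_bins-1 from the lightest peak (M, M+1, M+2, ...).
    """

    peaks: tuple[tuple[float, float], ...]
    binned: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        abunds = [a for _, a in self.peaks]
        if not abunds or abs(max(abunds) - 1.0) > 1e-9:
            raise ValueError("base peak abundance must be 1.0")
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("peak masses must be strictly increasing")

    def binned_ratios(self) -> dict[int, float]:
        return dict(self.binned)


def _single_atom(el: str) -> list[tuple[float, float]]:
    return [(m, a) for m, a in ISOTOPES[el] if a > 0]


def _merge(peaks: list[tuple[float, float]], tol: float = 1e-7) -> list[tuple[float, float]]:
    peaks.sort()
    out: list[list[float]] = []
    for m, a in peaks:
        if out and m - out[-1][0] <= tol:
            # abundance-weighted centroid of coincident fine peaks
            tot = out[-1][1] + a
            out[-1][0] = (out[-1][0] * out[-1][1] + m * a) / tot
            out[-1][1] = tot
        else:
            out.append([m, a])
    return [(m, a) for m, a in out]


def _convolve(
    x: list[tuple[float, float]], y: list[tuple[float, float]], prune: float
) -> list[tuple[float, float]]:
    peaks = [(mx + my, ax * ay) for (mx, ax), (my, ay) in itertools.product(x, y)]
    peaks = _merge(peaks)
    top = max(a for _, a in peaks)
    return [(m, a) for m, a in peaks if a >= prune * top]


def _element_pattern(el: str, n: int, prune: float) -> list[tuple[float, float]]:
    """Distribution of n atoms of one element by binary-exponentiation convolution."""
    base = _single_atom(el)
    result: list[tuple[float, float]] | None = None
    power = base
    while n:
        if n & 1:
            result = power if result is None else _convolve(result, power, prune)
        n >>= 1
        if n:
            power = _convolve(power, power, prune)
    assert result is not None
    return result


def isotope_pattern(
    counts: ElementCounts,
    prune_threshold: float = 1e-5,
    max_bins: int = 3,
) -> IsotopePattern:
    """Fine-structure isotope pattern of a formula.

    Per-element isotopologue distributions are built by convolution over the
    natural abundances and convolved across elements; fine peaks below
    ``prune_threshold`` of the base peak are dropped and the survivors are
    binned into nominal mass offsets 0..``max_bins``-1.  Results are cached
    per formula.
    """
    return _isotope_pattern_cached(
        tuple(sorted(counts.items())), prune_threshold, max_bins
    )


@functools.lru_cache(maxsize=16384)
def _isotope_pattern_cached(
    items: tuple[tuple[str, int], ...], prune_threshold: float, max_bins: int
) -> IsotopePattern:
    counts: ElementCounts = dict(items)
    if not 0 < prune_threshold <= 0.01:
        raise ValueError("prune_threshold must be in (0, 0.01]")
    if max_bins < 2:
        raise ValueError("max_bins must be >= 2")
    if not counts:
        raise ValueError("empty formula has no isotope pattern")

    # prune conservatively during convolution; final prune below
    work = prune_threshold / 10.0
    peaks: list[tuple[float, float]] | None = None
    for el, n in sorted(counts.items()):
        if el not in ISOTOPES:
            raise ValueError(f"unknown element symbol {el!r}")
        dist = _element_pattern(el, n, work)
        peaks = dist if peaks is None else _convolve(peaks, dist, work)
    assert peaks is not None

    base = max(a for _, a in peaks)
    rel = [(m, a / base) for m, a in peaks if a / base >= prune_threshold]
    rel.sort()
    m0 = rel[0][0]
    # the bin window starts at the lightest peak; the base peak itself can sit
    # beyond it for heavy-isotope-rich formulas, so peaks are kept in full
    bins: dict[int, float] = {}
    for m, a in rel:
        k = round(m - m0)
        if k < max_bins:
            bins[k] = bins.get(k, 0.0) + a
    return IsotopePattern(
        peaks=tuple(rel),
        binned=tuple(sorted(bins.items())),
    )
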