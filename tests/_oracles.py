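"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations kept separate from the package code paths
they check.
"""

from __future__ import annotations

import itertools
import math

from phytoscreen.elements import ISOTOPES


def brute_isotope_binned(counts: dict[str, int], max_bins: int = 3) -> dict[int, float]:
    """Exhaustive isotopologue enumeration, grouped by indistinguishable atoms.

    For each element the isotope count-vectors are enumerated with their exact
    multinomial probabilities; the cartesian product over elements gives every
    isotopologue.  No pruning.  Returns nominal-offset bins normalised to the
    base (most abundant) peak.
    """
    per_element = []
    for el, n in sorted(counts.items()):
        isotopes = ISOTOPES[el]
        combos = []
        for ks in _compositions(n, len(isotopes)):
            coef = math.factorial(n)
            prob = 1.0
            mass = 0.0
            for k, (m, p) in zip(ks, isotopes):
                coef //= math.factorial(k)
                prob *= p**k
                mass += k * m
            combos.append((mass, coef * prob))
        per_element.append(combos)

    peaks: dict[float, float] = {}
    for combo in itertools.product(*per_element):
        mass = sum(m for m, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        key = round(mass, 9)
        peaks[key] = peaks.get(key, 0.0) + prob

    base = max(peaks.values())
    m0 = min(peaks)
    bins: dict[int, float] = {}
    for m, p in peaks.items():
        k = round(m - m0)
        if k < max_bins:
            bins[k] = bins.get(k, 0.0) + p / base
    return bins


def _compositions(n: int, k: int):
    """All ways to write n as an ordered sum of k non-negative integers."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def brute_force_screen(features, ion_table, cfg):
    """All-pairs screening: the oracle for the sorted-table binary search."""
    from phytoscreen.screening import score_candidate

    accepted = []
    for feature in features:
        for ion in ion_table:
            if ion.adduct.polarity != feature.polarity:
                continue
            match = score_candidate(feature, ion, cfg)
            if match is not None and match.combined_score >= cfg.accept_threshold:
                accepted.append(match)
    return accepted
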