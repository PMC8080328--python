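"""Isotope masses and natural abundances for the elements handled by the kernel.

Values are IUPAC/CIAAW 2021 atomic masses (Da, >= 6 decimal places) and
representative natural abundances.  The first isotope listed for each element
is the lightest, which for every element here is also the most abundant, so
the monoisotopic mass of a formula is the abundance-weighted base peak.
"""

from __future__ import annotations

# electron and proton rest masses, Da
ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466621

#: element -> tuple of (exact mass, natural abundance), lightest first
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503224, 0.999885), (2.01410177812, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483521, 0.0107)),
    "N": ((14.00307400446, 0.99636), (15.00010889894, 0.00364)),
    "O": (
        (15.99491461960, 0.99757),
        (16.99913175664, 0.00038),
        (17.99915961287, 0.00205),
    ),
    "F": ((18.99840316273, 1.0),),
    "Na": ((22.98976928, 1.0),),
    "P": ((30.97376199842, 1.0),),
    "S": (
        (31.9720711744, 0.9499),
        (32.9714589099, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ),
    "Cl": ((34.968852682, 0.7576), (36.965902603, 0.2424)),
    "K": (
        (38.9637064864, 0.932581),
        (39.963998166, 0.000117),
        (40.9618252579, 0.067302),
    ),
}

#: lightest-isotope exact mass per element
MONOISOTOPIC: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}
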