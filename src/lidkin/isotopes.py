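"""Isotope constants and elemental-formula mass arithmetic.

Silver's two stable isotopes (¹⁰⁷Ag 51.839%, ¹⁰⁹Ag 48.161%) produce the
characteristic two-peak pattern ~2 Th apart in singly charged
silver-containing ions that the classifier in :mod:`lidkin.fragments`
exploits.
"""

from __future__ import annotations

import re

# Exact isotope masses (Da) and natural abundances.
AG107_MASS = 106.905092
AG109_MASS = 108.904756
AG107_ABUNDANCE = 0.51839
AG109_ABUNDANCE = 0.48161

#: m/z spacing of the Ag doublet for z = 1.
AG_DOUBLET_SPLIT = AG109_MASS - AG107_MASS

#: Expected high/low intensity ratio of a singly charged Ag doublet.
AG_DOUBLET_RATIO = AG109_ABUNDANCE / AG107_ABUNDANCE

# Integer (nominal) masses of the most abundant isotope.
NOMINAL_MASSES = {
    "H": 1,
    "C": 12,
    "N": 14,
    "O": 16,
    "S": 32,
    "P": 31,
    "Ag": 107,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def nominal_mass(formula: str) -> int:
    """Nominal (integer-isotope) mass of an elemental formula.

    >>> nominal_mass("C9H7N")   # indole side chain lost on Cα–Cβ cleavage
    129
    """
    pos = 0
    total = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos or not match.group(1):
            raise ValueError(f"cannot parse formula {formula!r}")
        element, count = match.group(1), match.group(2)
        if element not in NOMINAL_MASSES:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        total += NOMINAL_MASSES[element] * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


#: Neutral losses marking radical-tryptophan fragmentation: Cα–Cβ cleavage
#: sheds the indole side chain (C9H7N, 129 Da); a radical rearrangement
#: sheds the Trp-containing C-terminus (185 Da).
INDOLE_LOSS = nominal_mass("C9H7N")
TRP_CTERM_LOSS = 185
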