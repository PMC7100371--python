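"""Reference proton-transfer time constants for His/Trp peptides.

Published replicate fits (τ₂, σ, both in μs) from pump–probe
photofragmentation measurements on silver-cationized peptides of the form
H-Xn-W (and sequence-reversed variants), grouped by family: pentapeptides,
poly-glycines, poly-alanines and poly-prolines.  Each system was measured
on several days; the table stores the per-day bootstrap fits alongside
the published inverse-variance weighted means, so the aggregation step
can be exercised against printed values.

Systems whose decay exceeded the 20 ms delay window are censored and
carry only a lower bound (τ₂ > 5000 μs): the His-free controls G₂W and
G₃W (no proton acceptor, no decay) and HA₆W (helix formation competing
with proton transfer).
"""

from __future__ import annotations

__all__ = [
    "REPLICATE_FITS",
    "PUBLISHED_MEANS",
    "CENSORED_SYSTEMS",
    "CENSOR_BOUND_US",
    "FAMILIES",
]

#: Per-day replicate fits, μs: {system: [(tau2, sigma), ...]}.
REPLICATE_FITS: dict[str, list[tuple[float, float]]] = {
    "HGAGW": [(1041, 215), (699, 27)],
    "HGIGW": [(634, 24)],
    "HGLGW": [(589, 30), (681, 47)],
    "HG1W": [(356, 295)],
    "HG3W": [(563, 38), (482, 74), (448, 35), (478, 56), (411, 64)],
    "HG5W": [(513, 26), (674, 40), (628, 46), (723, 59), (521, 56), (673, 53)],
    "HG8W": [(1139, 348), (775, 71), (726, 83), (1336, 539)],
    "WG8H": [(1199, 707), (853, 228), (990, 200)],
    "HA3W": [(662, 106), (700, 88), (1032, 82)],
    "HA5W": [(1184, 339), (1744, 190), (1604, 94), (1262, 84)],
    "HP3W": [(449, 52), (570, 100), (770, 43), (1266, 159)],
    "HP5W": [(646, 589), (588, 236), (1921, 896), (2371, 2001)],
    "WP5H": [(1374, 158), (1575, 411), (1313, 303)],
}

#: Published weighted means, μs: {system: (tau2_mean, sigma)}.
PUBLISHED_MEANS: dict[str, tuple[float, float]] = {
    "HGAGW": (704, 27),
    "HGIGW": (634, 24),
    "HGLGW": (615, 25),
    "HG1W": (356, 295),
    "HG3W": (487, 21),
    "HG5W": (591, 17),
    "HG8W": (763, 53),
    "WG8H": (942, 147),
    "HA3W": (825, 52),
    "HA5W": (1438, 58),
    "HP3W": (657, 31),
    "HP5W": (690, 212),
    "WP5H": (1383, 133),
}

#: Systems reported only as a lower bound on τ₂.
CENSORED_SYSTEMS: tuple[str, ...] = ("G2W", "G3W", "HA6W")
CENSOR_BOUND_US: float = 5000.0

FAMILIES: dict[str, tuple[str, ...]] = {
    "controls": ("G2W", "G3W"),
    "pentapeptides": ("HGAGW", "HGIGW", "HGLGW"),
    "polyglycines": ("HG1W", "HG3W", "HG5W", "HG8W", "WG8H"),
    "polyalanines": ("HA3W", "HA5W", "HA6W"),
    "polyprolines": ("HP3W", "HP5W", "WP5H"),
}
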