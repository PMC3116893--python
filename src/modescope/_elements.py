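"""Bundled per-element constants.

Van der Waals radii (Bondi-style, Å) and atomic masses (Da) for the
elements that occur in protein structures. Kept as a static table so that
structure preparation is fully deterministic and needs no external lookup.
"""

from __future__ import annotations

VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 1.97,
    "NA": 2.27,
    "K": 2.75,
    "SE": 1.90,
}

MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "NA": 22.990,
    "K": 39.098,
    "SE": 78.971,
}

#: fallback for unknown elements (generic heavy atom)
DEFAULT_RADIUS = 1.70
DEFAULT_MASS = 12.011


def vdw_radius(element: str) -> float:
    return VDW_RADIUS.get(element.upper(), DEFAULT_RADIUS)


def mass(element: str) -> float:
    return MASS.get(element.upper(), DEFAULT_MASS)
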