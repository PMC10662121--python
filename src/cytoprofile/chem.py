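"""Molecular-formula arithmetic for high-resolution MS support.

Monoisotopic (most-abundant-isotope) masses only, as used for HRESIMS
adduct calculations; average masses are deliberately not implemented.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "degree_of_unsaturation",
    "ELECTRON_MASS",
]

# Monoisotopic masses of the most abundant isotope, Da (CODATA/AME2020,
# >= 6 decimal places). Extend here if an element is missing.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825032,
    "D": 2.014101778,
    "B": 11.009305167,
    "C": 12.0,
    "N": 14.003074004,
    "O": 15.994914620,
    "F": 18.998403163,
    "Na": 22.989769282,
    "Mg": 23.985041697,
    "Si": 27.976926535,
    "P": 30.973761998,
    "S": 31.972071174,
    "Cl": 34.968852682,
    "K": 38.963706486,
    "Ca": 39.962590863,
    "Fe": 55.934936326,
    "Br": 78.918337600,
    "I": 126.904471900,
}

ELECTRON_MASS = 0.000548580  # Da
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

HALOGENS = {"F", "Cl", "Br", "I"}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition plus net charge (default neutral)."""

    element_counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise ValueError("formula must contain at least one element")
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts, self.charge + other.charge)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        counts = self.element_counts
        order = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
        order += sorted(el for el in counts if el not in order)
        return "".join(
            f"{el}{counts[el]}" if counts[el] != 1 else el
            for el in order
            if counts[el] > 0
        )


def parse_formula(text: str) -> MolecularFormula:
    """Parse a plain formula string like ``"C15H28O2"``.

    Element symbols with optional multi-digit counts, in any order;
    repeated symbols accumulate. No parentheses or isotope labels.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula at {text[pos:]!r}")
    return MolecularFormula(counts)


def _as_formula(f: "MolecularFormula | str") -> MolecularFormula:
    return parse_formula(f) if isinstance(f, str) else f


def monoisotopic_mass(f: "MolecularFormula | str") -> float:
    """Exact mass in Da using most-abundant-isotope masses.

    For a charged species the electron mass is subtracted per positive
    charge (added per negative charge).
    """
    f = _as_formula(f)
    mass = sum(n * MONOISOTOPIC_MASS[el] for el, n in f.element_counts.items())
    return mass - f.charge * ELECTRON_MASS


def mz_deprotonated(f: "MolecularFormula | str") -> float:
    """m/z of the [M-H]- ion: neutral mass minus a proton, |z| = 1."""
    return monoisotopic_mass(f) - PROTON_MASS


def degree_of_unsaturation(f: "MolecularFormula | str") -> float:
    """Rings-plus-pi-bonds (DBE) from the formula.

    DBE = (2C + 2 + N - H - X)/2 with halogens counted like hydrogen
    and divalent elements (O, S) ignored. Half-integral for radicals.
    """
    f = _as_formula(f)
    c = f.element_counts.get("C", 0)
    n = f.element_counts.get("N", 0)
    h = f.element_counts.get("H", 0) + f.element_counts.get("D", 0)
    x = sum(f.element_counts.get(el, 0) for el in HALOGENS)
    return (2 * c + 2 + n - h - x) / 2
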