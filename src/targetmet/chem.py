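"""Monoisotopic masses and adduct m/z computation from molecular formulas.

Element masses are the monoisotopic (most abundant isotope) atomic masses
from the IUPAC/CODATA 2021 atomic mass evaluation, embedded statically so
no network or external table is required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ElementCounts",
    "AdductSpec",
    "FormulaError",
    "ADDUCTS",
    "PROTON_MASS",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "resolve_mz",
]

# Monoisotopic masses in Da (AME2020 / IUPAC-CIAAW).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "Se": 79.9165213,
    "Si": 27.9769265325,
}

#: Mass of a bare proton in Da. Protonation adds a proton, not a hydrogen
#: atom: the electron stays behind.
PROTON_MASS = 1.00727646688

ElementCounts = dict[str, int]


class FormulaError(ValueError):
    """Raised for malformed or unknown-element molecular formulas."""


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: name, mass delta in Da and signed charge."""

    name: str
    delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


# Single-charge adducts; deltas are exact ion-mass minus neutral-mass
# differences (electron mass accounted for via the proton-mass convention).
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M+Na]+": AdductSpec("[M+Na]+", 22.98922070, +1),
    "[M+K]+": AdductSpec("[M+K]+", 38.96315843, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", 18.03382555, +1),
    "[M+Cl]-": AdductSpec("[M+Cl]-", 34.96940126, -1),
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def get_adduct(name: str) -> AdductSpec:
    """Look up an adduct by name; the Unicode minus sign is accepted."""
    key = name.replace("−", "-").strip()
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}"
        ) from None


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-style molecular formula into element counts.

    Parameters
    ----------
    formula:
        e.g. ``"C15H12I3NO4"``. Element symbols with optional integer
        counts; no parentheses or isotope labels.

    Raises
    ------
    FormulaError
        On malformed tokens or element symbols without a mass entry.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: ElementCounts = {}
    pos = 0
    text = formula.strip()
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula!r}: unparseable at {text[pos:]!r}"
            )
        elem, count_s = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element {elem!r} in formula {formula!r}"
            )
        n = int(count_s) if count_s else 1
        if n < 1:
            raise FormulaError(
                f"non-positive count for {elem!r} in formula {formula!r}"
            )
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    return counts


def formula_to_string(counts: ElementCounts) -> str:
    """Canonical Hill-order string: C, H, then other elements alphabetically."""
    parts: list[str] = []
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    for elem in order:
        n = counts[elem]
        parts.append(elem if n == 1 else f"{elem}{n}")
    return "".join(parts)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Sum of per-element monoisotopic masses times counts, in Da."""
    total = 0.0
    for elem, n in counts.items():
        try:
            total += MONOISOTOPIC_MASS[elem] * n
        except KeyError:
            raise FormulaError(
                f"element {elem!r} missing from the monoisotopic mass table"
            ) from None
    return total


def adduct_mz(mass: float, adduct: AdductSpec | str) -> float:
    """m/z of the ion formed from a neutral of the given monoisotopic mass.

    ``(mass + delta) / |charge|``.
    """
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return (mass + adduct.delta) / abs(adduct.charge)


def resolve_mz(formula: str, adduct: AdductSpec | str) -> float:
    """Convenience: formula string + adduct name -> theoretical m/z."""
    return adduct_mz(monoisotopic_mass(parse_formula(formula)), adduct)
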