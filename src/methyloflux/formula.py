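"""Elemental composition strings: parsing, carbon counting, molar mass.

Formulas follow the Hill convention used by BIGG/SBML models, e.g.
``C6H12O6`` or ``C21H26N7O17P3``. An element symbol is one uppercase letter
optionally followed by one lowercase letter, so ``Cl``/``Co``/``Ca`` are not
carbon.
"""

from __future__ import annotations

import re

__all__ = [
    "FormulaError",
    "parse_formula",
    "carbon_count",
    "molar_mass",
    "ATOMIC_WEIGHTS",
]

# standard atomic weights (IUPAC abridged), enough for small-molecule work
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
    "Cl": 35.45,
    "Ca": 40.078,
    "Mg": 24.305,
    "Fe": 55.845,
    "Co": 58.933,
    "Zn": 65.38,
    "Se": 78.971,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for a composition string that is not a valid Hill formula."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style composition string into an element → count map.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not isinstance(formula, str) or formula == "":
        raise FormulaError(f"not a composition string: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable token {formula[pos:match.start()]!r} in {formula!r}"
            )
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable token {formula[pos:]!r} in {formula!r}")
    return counts


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a composition string.

    ``C`` followed by a lowercase letter (Cl, Co, Ca, ...) is a different
    element and contributes zero.
    """
    return parse_formula(formula).get("C", 0)


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    mass = 0.0
    for element, n in parse_formula(formula).items():
        try:
            mass += ATOMIC_WEIGHTS[element] * n
        except KeyError:
            raise FormulaError(f"no atomic weight for element {element!r}")
    return mass
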