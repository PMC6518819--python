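"""Elemental-formula arithmetic and exact monoisotopic mass / ion m/z.

Masses are monoisotopic: each element contributes the mass of its most
abundant isotope.  Positive-ion m/z subtracts one electron mass per charge,
which is required to reproduce high-resolution "calcd" values to four
decimal places (omitting it misses by ~0.0005 Th for singly charged ions).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "ELECTRON_MASS",
    "MolecularFormula",
    "IonSpec",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "isotope_masses",
]

#: CODATA electron rest mass in Da.
ELECTRON_MASS = 0.000548579909

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


def isotope_masses(path: str | None = None) -> dict[str, float]:
    """Most-abundant-isotope masses (Da) keyed by element symbol.

    By default the packaged table is used; ``path`` points at a
    two-column CSV (element,mass) to override it.
    """
    if path is None:
        src = resources.files("nrpsmine.data").joinpath("isotopes.csv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out: dict[str, float] = {}
    for row in csv.DictReader(text.splitlines()):
        out[row["element"]] = float(row["mass"])
    return out


_ISOTOPES = isotope_masses()


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count map; counts are non-negative integers."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in _ISOTOPES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return formula_combine(self, other, +1)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return formula_combine(self, other, -1)

    def __str__(self) -> str:
        return self.to_hill()

    def __repr__(self) -> str:
        return f"MolecularFormula({self.to_hill()!r})"

    def to_hill(self) -> str:
        """Hill-order string: C first, then H, then the rest alphabetically."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


#: Frequently reused building blocks.
WATER = MolecularFormula({"H": 2, "O": 1})
PROTON = MolecularFormula({"H": 1})


@dataclass(frozen=True)
class IonSpec:
    """A charged species: the formula of the intact ion (protons included as
    H atoms) and its positive charge state."""

    formula: MolecularFormula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string like ``"C44H75N9O17"``.

    Counts default to 1 (``"H2O"`` → {H:2, O:1}).  Unknown element symbols
    and empty or partially unparseable input raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos or not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in _ISOTOPES:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def formula_combine(a: MolecularFormula, b: MolecularFormula, sign: int = +1) -> MolecularFormula:
    """Count-wise sum (sign=+1) or difference (sign=-1) of two formulas.

    Subtraction that would drive any element count negative raises
    :class:`FormulaError` naming the element.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    out = dict(a.counts)
    for el, n in b.counts.items():
        new = out.get(el, 0) + sign * n
        if new < 0:
            raise FormulaError(f"subtraction drives element {el} negative ({new})")
        out[el] = new
    return MolecularFormula(out)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, in Da."""
    return sum(_ISOTOPES[el] * n for el, n in f.counts.items())


def ion_mz(ion: IonSpec) -> float:
    """m/z of a positive ion whose formula already includes its protons.

    m/z = (monoisotopic mass − charge × m_e) / charge.
    """
    return (monoisotopic_mass(ion.formula) - ion.charge * ELECTRON_MASS) / ion.charge


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error in parts per million."""
    if calculated <= 0:
        raise ValueError(f"calculated m/z must be positive, got {calculated}")
    return (observed - calculated) / calculated * 1e6
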