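"""Residue library and lipodepsipeptide construction.

Residues are stored as in-chain formulas (free monomer minus one water), so
a linear peptide is Σ residues + H2O and a macrolactone is simply Σ
residues: ring closure through the ester between the lipid β-hydroxyl and
the C-terminal carboxyl removes exactly the water the linear form carries.

The library covers the 20 proteinogenic amino acids plus allo-threonine,
homoserine and the β-hydroxy-γ-methyl hexadecanoic acid (HMHDA) lipid
found in Phomafungin-family lipodepsipeptides.  Chirality is metadata
only — it never changes a formula or a mass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

from .chem import WATER, MolecularFormula, monoisotopic_mass, parse_formula

__all__ = [
    "Residue",
    "Peptide",
    "ResidueLookupError",
    "TopologyError",
    "CHIRALITIES",
    "residue_library",
    "library_residue",
    "build_peptide",
    "hydrolyze",
    "cyclize",
    "carbon_count",
]

CHIRALITIES = ("L", "D", "achiral", "unspecified")


class ResidueLookupError(KeyError):
    """Unknown residue code."""


class TopologyError(ValueError):
    """Peptide topology constraint violated."""


@dataclass(frozen=True)
class Residue:
    name: str
    residue_formula: MolecularFormula
    chirality: str = "unspecified"
    kind: str = "amino_acid"

    def __post_init__(self) -> None:
        if not self.residue_formula:
            raise ValueError(f"residue {self.name}: empty formula")
        if self.chirality not in CHIRALITIES:
            raise ValueError(f"residue {self.name}: bad chirality {self.chirality!r}")
        if self.kind not in ("amino_acid", "lipid"):
            raise ValueError(f"residue {self.name}: bad kind {self.kind!r}")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.residue_formula)

    def with_chirality(self, chirality: str) -> "Residue":
        return replace(self, chirality=chirality)


def residue_library(path: str | None = None) -> dict[str, Residue]:
    """Load the residue library (packaged CSV by default).

    Columns: code, formula, default_chirality, kind.
    """
    if path is None:
        text = resources.files("nrpsmine.data").joinpath("residues.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lib: dict[str, Residue] = {}
    for row in csv.DictReader(text.splitlines()):
        lib[row["code"]] = Residue(
            name=row["code"],
            residue_formula=parse_formula(row["formula"]),
            chirality=row["default_chirality"],
            kind=row["kind"],
        )
    return lib


_LIBRARY = residue_library()


def library_residue(code: str, chirality: str | None = None) -> Residue:
    """Fetch a residue by code, optionally overriding its chirality."""
    try:
        res = _LIBRARY[code]
    except KeyError:
        known = ", ".join(sorted(_LIBRARY))
        raise ResidueLookupError(f"unknown residue code {code!r}; known: {known}") from None
    if chirality is not None:
        res = res.with_chirality(chirality)
    return res


def _ester_capable(res: Residue) -> bool:
    # the macrolactone ester donor: the lipid β-OH, or a hydroxy side chain
    return res.kind == "lipid" or res.name in ("Ser", "Thr", "allo-Thr", "Homoser", "Tyr")


@dataclass(frozen=True)
class Peptide:
    """Ordered residues with linear or macrolactone topology."""

    residues: tuple[Residue, ...]
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if self.topology not in ("linear", "macrolactone"):
            raise TopologyError(f"bad topology {self.topology!r}")
        if self.topology == "macrolactone":
            if len(self.residues) < 2:
                raise TopologyError("macrolactone requires at least 2 residues")
            if not _ester_capable(self.residues[0]):
                raise TopologyError(
                    f"macrolactone requires an ester-capable first residue, got {self.residues[0].name}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def formula(self) -> MolecularFormula:
        total = MolecularFormula()
        for res in self.residues:
            total = total + res.residue_formula
        if self.topology == "linear":
            total = total + WATER
        return total

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def codes(self) -> list[str]:
        return [r.name for r in self.residues]


def build_peptide(
    specs: Iterable[str | tuple[str, str] | Residue],
    topology: str = "linear",
) -> Peptide:
    """Build a peptide from residue specs.

    Each spec is a residue code, a (code, chirality) pair, or a
    :class:`Residue`.  Topology invariants are enforced at construction.
    """
    residues: list[Residue] = []
    for spec in specs:
        if isinstance(spec, Residue):
            residues.append(spec)
        elif isinstance(spec, str):
            residues.append(library_residue(spec))
        else:
            code, chirality = spec
            residues.append(library_residue(code, chirality))
    return Peptide(tuple(residues), topology)


def hydrolyze(p: Peptide) -> Peptide:
    """Open a macrolactone: same residue order, linear topology (+H2O)."""
    if p.topology != "macrolactone":
        raise TopologyError("peptide is already linear")
    return Peptide(p.residues, "linear")


def cyclize(p: Peptide) -> Peptide:
    """Close a linear lipopeptide into a macrolactone (−H2O)."""
    if p.topology != "linear":
        raise TopologyError("peptide is already a macrolactone")
    return Peptide(p.residues, "macrolactone")


def carbon_count(p: Peptide) -> int:
    """Number of carbon atoms in the peptide formula (cf. 13C resonances)."""
    return p.formula["C"]
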