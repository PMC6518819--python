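"""Stereochemistry assignment by Marfey's method (L-FDAA derivatization).

Hydrolysate amino acids derivatized with Marfey's reagent are assigned a
D/L configuration by comparing LC retention times against a table of
derivatized standards.  Acid hydrolysis converts asparagine to aspartate
and glutamine to glutamate, so the product side of a consistency check is
mapped Asn→Asp / Gln→Glu before comparison.  Glycine is achiral and
therefore untestable; the lipid is not derivatized and is excluded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .cluster import PredictedProduct

__all__ = [
    "StandardsTable",
    "MarfeyAssignment",
    "ConsistencyReport",
    "HYDROLYSIS_MAP",
    "assign_peaks",
    "infer_ratio",
    "consistency_check",
]

#: Residues transformed by acid hydrolysis before derivatization.
HYDROLYSIS_MAP = {"Asn": "Asp", "Gln": "Glu"}


@dataclass
class StandardsTable:
    """Derivatized-standard retention times: label (with chirality) → minutes."""

    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in standards table")
        for lab, rt in self.entries:
            if rt <= 0:
                raise ValueError(f"standard {lab}: retention time must be positive")

    @classmethod
    def packaged(cls) -> "StandardsTable":
        text = resources.files("nrpsmine.data").joinpath("marfey_standards.csv").read_text()
        return cls.from_csv_text(text)

    @classmethod
    def from_csv_text(cls, text: str) -> "StandardsTable":
        rows = list(csv.DictReader(text.splitlines()))
        return cls([(r["label"], float(r["rt"])) for r in rows])

    @classmethod
    def from_csv(cls, path: str) -> "StandardsTable":
        with open(path) as fh:
            return cls.from_csv_text(fh.read())

    def rt(self, label: str) -> float:
        for lab, rt in self.entries:
            if lab == label:
                return rt
        raise KeyError(label)


def split_label(label: str) -> tuple[str | None, str]:
    """'D-allo-Thr' → ('D', 'allo-Thr'); 'Gly' → (None, 'Gly')."""
    if label.startswith(("L-", "D-")):
        return label[0], label[2:]
    return None, label


@dataclass
class MarfeyAssignment:
    rt: float
    area: float
    analyte: str | None  # standard label, None if unmatched
    delta_rt: float | None
    residue: str | None = None  # analyte residue after reverse hydrolysis naming
    ambiguous_with: list[str] = field(default_factory=list)

    @property
    def matched(self) -> bool:
        return self.analyte is not None

    @property
    def chirality(self) -> str | None:
        if self.analyte is None:
            return None
        chir, _ = split_label(self.analyte)
        return chir or "achiral"


def assign_peaks(
    sample_peaks: Iterable[tuple[float, float]],
    standards: StandardsTable,
    tol_rt: float = 0.05,
    resolution: float = 0.02,
) -> list[MarfeyAssignment]:
    """Nearest-standard assignment of chromatogram peaks within ``tol_rt``.

    A peak matching two standards whose |Δrt| differ by less than
    ``resolution`` is flagged ambiguous (both candidates recorded).
    Unmatched peaks are reported with ``analyte=None``.  Assignments are
    independent per peak, so input order is irrelevant.
    """
    if tol_rt <= 0:
        raise ValueError("tol_rt must be positive")
    if not standards.entries:
        raise ValueError("empty standards table")
    out: list[MarfeyAssignment] = []
    for rt, area in sample_peaks:
        within = sorted(
            ((abs(rt - srt), lab) for lab, srt in standards.entries if abs(rt - srt) <= tol_rt),
        )
        if not within:
            out.append(MarfeyAssignment(rt, area, None, None))
            continue
        d0, best = within[0]
        ambiguous = [lab for d, lab in within[1:] if d - d0 < resolution]
        _, analyte_res = split_label(best)
        out.append(
            MarfeyAssignment(
                rt=rt,
                area=area,
                analyte=best,
                delta_rt=d0,
                residue=analyte_res,
                ambiguous_with=ambiguous,
            )
        )
    return out


def infer_ratio(
    assignments: list[MarfeyAssignment],
    rel_tol: float = 0.15,
    max_part: int = 6,
) -> tuple[int, ...]:
    """Smallest integer ratio of peak areas among assignments of one residue.

    Areas are scaled by the smallest; each scaled area must round to a
    positive integer within ``rel_tol`` relative tolerance.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two assignments sharing a residue identity")
    areas = [a.area for a in assignments]
    if any(x <= 0 for x in areas):
        raise ValueError("areas must be positive")
    smallest = min(areas)
    scaled = [x / smallest for x in areas]
    ints = [max(1, round(s)) for s in scaled]
    for s, k in zip(scaled, ints):
        if k > max_part or abs(s - k) / k > rel_tol:
            raise ValueError(f"areas do not reduce to a small integer ratio (got {s:.3f} vs {k})")
    g = math.gcd(*ints)
    return tuple(k // g for k in ints)


@dataclass
class ConsistencyReport:
    per_residue: dict[str, str] = field(default_factory=dict)  # residue → agree|disagree|untestable
    details: dict[str, str] = field(default_factory=dict)

    @property
    def all_agree(self) -> bool:
        return all(v in ("agree", "untestable") for v in self.per_residue.values())


def _family(name: str) -> str:
    """Chromatographically distinguished isoforms share one residue family."""
    if name in ("Thr", "allo-Thr"):
        return "Thr"
    return name


def _product_composition(product: PredictedProduct) -> dict[str, dict[tuple[str, str], int]]:
    """family → (isoform name, chirality) → count; lipid excluded,
    Asn/Gln mapped to their hydrolysis products."""
    comp: dict[str, dict[tuple[str, str], int]] = {}
    for res in product.peptide.residues:
        if res.kind == "lipid":
            continue
        name = HYDROLYSIS_MAP.get(res.name, res.name)
        fam = _family(name)
        comp.setdefault(fam, {})
        key = (name, res.chirality)
        comp[fam][key] = comp[fam].get(key, 0) + 1
    return comp


def consistency_check(
    assignments: list[MarfeyAssignment],
    product: PredictedProduct,
) -> ConsistencyReport:
    """Compare Marfey assignments with a predicted product's composition.

    For each chiral residue family of the product the observed analytes
    (isoform + chirality, e.g. D-allo-Thr vs L-Thr) — and, where several
    peaks share the family, the observed area ratio — must match the
    product's multiplicities.  Achiral residues (Gly) are untestable;
    families with no observed peak are untestable too.
    """
    report = ConsistencyReport()
    comp = _product_composition(product)
    by_family: dict[str, list[MarfeyAssignment]] = {}
    for a in assignments:
        if a.matched and a.residue:
            by_family.setdefault(_family(a.residue), []).append(a)
    for family, iso_counts in comp.items():
        chiralities = {chir for _, chir in iso_counts}
        if chiralities <= {"achiral", "unspecified"}:
            report.per_residue[family] = "untestable"
            report.details[family] = "achiral residue; Marfey cannot test it"
            continue
        obs = by_family.get(family, [])
        if not obs:
            report.per_residue[family] = "untestable"
            report.details[family] = "no observed peak for this residue"
            continue
        obs_keys = {(a.residue, a.chirality) for a in obs}
        exp_keys = {k for k in iso_counts if k[1] in ("L", "D")}
        if obs_keys != exp_keys:
            report.per_residue[family] = "disagree"
            report.details[family] = (
                f"observed analytes {sorted(obs_keys)} vs predicted {sorted(exp_keys)}"
            )
            continue
        if len(exp_keys) > 1:
            # multiplicity check via area ratio, e.g. 2x L-Ser : 1x D-Ser
            by_key: dict[tuple[str, str], float] = {}
            for a in obs:
                key = (a.residue, a.chirality)
                by_key[key] = by_key.get(key, 0.0) + a.area
            order = sorted(exp_keys)
            pseudo = [
                MarfeyAssignment(0.0, by_key[k], analyte=str(k), delta_rt=0.0) for k in order
            ]
            try:
                ratio = infer_ratio(pseudo)
            except ValueError:
                report.per_residue[family] = "disagree"
                report.details[family] = "areas do not form a small integer ratio"
                continue
            expected = tuple(iso_counts[k] for k in order)
            g = math.gcd(*expected)
            expected = tuple(k // g for k in expected)
            if ratio != expected:
                report.per_residue[family] = "disagree"
                report.details[family] = f"area ratio {ratio} vs predicted {expected}"
                continue
            report.details[family] = f"analytes and {':'.join(map(str, ratio))} ratio match"
        else:
            report.details[family] = f"observed {sorted(obs_keys)} matches prediction"
        report.per_residue[family] = "agree"
    return report
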