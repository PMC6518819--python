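"""NRPS cluster annotation: motif scanning, in-cluster profiles, module
grammar, condensation-domain subtyping and collinearity product prediction.

The domain grammar of a fungal lipopeptide NRPS is: an optional initiation
PCP (loads the activated fatty acid), repeated elongation blocks C-A-PCP
with an optional trailing epimerization (E) domain, and an optional
terminal condensation domain (CT) that releases and macrocyclizes the
product.  The collinearity rule maps module order onto residue order; an E
domain in a module epimerizes its residue to the D configuration.

Domain evidence here is motif- and profile-based: degenerate core motifs
(mA1–mA10 for adenylation domains, HHxxxDG and variants for condensation
domains, HHxxxDxVSW for epimerization domains) and position-specific
scoring profiles built from in-cluster domain alignments, with shuffle-based
empirical p-values instead of database E-values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .residues import Peptide, Residue, library_residue
from .specificity import CodeTable, SpecificityCode, lookup_code, nearest_code

__all__ = [
    "DEFAULT_MOTIFS",
    "MotifSet",
    "MotifMatch",
    "DomainHit",
    "ModuleArch",
    "Architecture",
    "ProfileModel",
    "ProfileHit",
    "PredictedProduct",
    "PredictionError",
    "scan_motifs",
    "build_profile",
    "scan_profile",
    "parse_architecture",
    "classify_cdomain",
    "predict_product",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: Packaged degenerate motifs.  'x' matches any residue; lowercase letters
#: are weakly conserved (match any residue, score bonus when they match).
DEFAULT_MOTIFS: dict[str, str] = {
    "mA1": "LTYxEL",
    "mA2": "LKAGxAYVPID",
    "mA3": "LAYxxYTSGTTGxPKG",
    "mA4": "FdxS",
    "mA5": "NxYGPTE",
    "mA6": "GELxIxGxGLARGYW",
    "mA7": "YKTGDQ",
    "mA8": "GrxDxQVKIRGxRVELEEVE",
    "mA9": "LpxYMIP",
    "mA10": "NGKIDR",
    "C": "HHxxxDG",
    "C-variant-SHG": "SHxxxDG",
    "C-variant-SHA": "SHxxxDA",
    "E": "HHxxxDxVSW",
}

#: Motif names considered non-canonical variants of the condensation motif.
C_VARIANT_MOTIFS = ("C-variant-SHG", "C-variant-SHA")


@dataclass(frozen=True)
class MotifMatch:
    name: str
    position: int  # 1-based start
    matched: str
    canonical: bool = True


@dataclass
class MotifSet:
    patterns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))

    def __post_init__(self) -> None:
        for name, pat in self.patterns.items():
            if not pat:
                raise ValueError(f"motif {name}: empty pattern")

    @staticmethod
    def _regex(pattern: str) -> re.Pattern:
        parts = []
        for ch in pattern:
            if ch == "x" or ch.islower():
                parts.append(".")
            else:
                parts.append(re.escape(ch))
        return re.compile("(?=(" + "".join(parts) + "))")


def scan_motifs(protein: str, motifs: MotifSet | None = None) -> list[MotifMatch]:
    """All exact degenerate motif matches, with 1-based start positions.

    Matches are reported in (position, motif-name) order; overlapping
    occurrences are all reported.  Variant condensation motifs are flagged
    non-canonical.
    """
    if not protein:
        raise ValueError("empty sequence")
    protein = protein.upper()
    if motifs is None:
        motifs = MotifSet()
    out: list[MotifMatch] = []
    for name in motifs.patterns:
        rx = MotifSet._regex(motifs.patterns[name])
        for m in rx.finditer(protein):
            out.append(
                MotifMatch(
                    name=name,
                    position=m.start() + 1,
                    matched=m.group(1),
                    canonical=name not in C_VARIANT_MOTIFS,
                )
            )
    out.sort(key=lambda h: (h.position, h.name))
    return out


# ---------------------------------------------------------------------------
# position-specific scoring profiles


@dataclass
class ProfileModel:
    """Per-column log-odds (base 2) over the 20-letter alphabet."""

    scores: np.ndarray  # shape (length, 20)
    background: np.ndarray  # shape (20,)
    pseudocount: float

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    def consensus(self) -> str:
        return "".join(AA20[i] for i in np.argmax(self.scores, axis=1))

    def max_score(self) -> float:
        return float(np.max(self.scores, axis=1).sum())


@dataclass(frozen=True)
class ProfileHit:
    start: int  # 1-based inclusive
    end: int
    score: float  # bits
    empirical_p: float | None = None


def build_profile(
    aligned: Sequence[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> ProfileModel:
    """Log-odds profile from a gapped alignment.

    Columns in which half or more of the sequences carry gaps are dropped;
    Laplace pseudocounts (``pseudocount`` total, spread by background) are
    added; the default background is uniform.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("ragged alignment: sequences differ in gapped length")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)
    cols = []
    n = len(aligned)
    for j in range(width):
        column = [s[j].upper() for s in aligned]
        gaps = sum(c == "-" for c in column)
        if gaps * 2 >= n:
            continue
        counts = np.zeros(20)
        for c in column:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        total = counts.sum()
        probs = (counts + pseudocount * background) / (total + pseudocount)
        cols.append(np.log2(probs / background))
    if not cols:
        raise ValueError("alignment has no usable columns")
    return ProfileModel(np.vstack(cols), background, pseudocount)


def _encode(seq: str) -> np.ndarray:
    idx = np.fromiter((_AA_INDEX.get(c, -1) for c in seq.upper()), dtype=np.int64, count=len(seq))
    return idx


def _best_window(profile: ProfileModel, encoded: np.ndarray) -> tuple[int, float]:
    """(0-based start, score) of the best-scoring ungapped window."""
    L = profile.length
    T = encoded.size
    n_win = T - L + 1
    # characters outside the alphabet score the column minimum
    col_min = profile.scores.min(axis=1)
    valid = encoded >= 0
    clipped = np.clip(encoded, 0, 19)
    scores = np.zeros(n_win)
    for j in range(L):
        row = np.where(valid, profile.scores[j, clipped], col_min[j])
        scores += row[j : j + n_win]
    best = int(np.argmax(scores))
    return best, float(scores[best])


def scan_profile(
    profile: ProfileModel,
    target: str,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ProfileHit:
    """Best ungapped window of the profile along the target, with an
    empirical p-value from residue-shuffled targets.

    p = (1 + #{shuffles with best score >= observed}) / (n_shuffles + 1),
    so a score no shuffle reaches gets p = 1/(n_shuffles+1).
    """
    if len(target) < profile.length:
        raise ValueError(
            f"target length {len(target)} shorter than profile length {profile.length}"
        )
    encoded = _encode(target)
    start0, score = _best_window(profile, encoded)
    p: float | None = None
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_shuffles):
            shuffled = rng.permutation(encoded)
            _, s = _best_window(profile, shuffled)
            if s >= score:
                ge += 1
        p = (1 + ge) / (n_shuffles + 1)
    return ProfileHit(start=start0 + 1, end=start0 + profile.length, score=score, empirical_p=p)


# ---------------------------------------------------------------------------
# module grammar


ELONGATION_DOMAINS = ("C", "A", "PCP", "E")
KNOWN_DOMAINS = ("A", "C", "PCP", "E", "CT", "KS", "AT", "DH", "cMT", "ER", "KR", "ACP")


@dataclass(frozen=True)
class DomainHit:
    domain_type: str
    start: int = 0  # 1-based inclusive protein coordinates; 0 = unknown
    end: int = 0
    score: float = 0.0
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.domain_type not in KNOWN_DOMAINS:
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if self.start > self.end:
            raise ValueError(f"domain {self.domain_type}: start > end")


@dataclass
class ModuleArch:
    index: int
    domains: list[DomainHit]
    role: str  # initiation | elongation | elongation+E | termination
    assigned_residue: str | None = None
    complete: bool = True
    missing_c_interval: tuple[int, int] | None = None

    @property
    def domain_types(self) -> list[str]:
        return [d.domain_type for d in self.domains]

    @property
    def has_E(self) -> bool:
        return "E" in self.domain_types

    @property
    def has_A(self) -> bool:
        return "A" in self.domain_types


@dataclass
class Architecture:
    modules: list[ModuleArch]
    diagnostics: list[str] = field(default_factory=list)

    @property
    def n_domains(self) -> int:
        return sum(len(m.domains) for m in self.modules)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def incomplete_modules(self) -> list[ModuleArch]:
        return [m for m in self.modules if not m.complete]

    def summary(self) -> str:
        lines = []
        for m in self.modules:
            flag = "" if m.complete else "  [incomplete — candidate missing C]"
            lines.append(f"M{m.index}: {'-'.join(m.domain_types)} ({m.role}){flag}")
        return "\n".join(lines)


def parse_architecture(hits: Sequence[DomainHit]) -> Architecture:
    """Group an ordered, non-overlapping domain-hit list into modules.

    Grammar: optional initiation PCP; repeated [C A PCP (E)?] elongation
    blocks; optional trailing CT termination.  An elongation module lacking
    its C domain is flagged incomplete, with the inter-domain interval in
    which the missing C should be sought (end of the previous module's last
    domain + 1 through start of the A domain − 1).  The parser is total:
    out-of-grammar domains produce diagnostics, never exceptions.
    """
    hits = list(hits)
    modules: list[ModuleArch] = []
    diagnostics: list[str] = []
    if not hits:
        diagnostics.append("empty domain list")
        return Architecture(modules, diagnostics)

    i = 0
    midx = 0
    # initiation: a leading PCP not preceded by C/A
    if hits[0].domain_type == "PCP":
        midx += 1
        modules.append(ModuleArch(midx, [hits[0]], "initiation"))
        i = 1

    current: list[DomainHit] | None = None

    def close_current() -> None:
        nonlocal current, midx
        if current is None:
            return
        types = [d.domain_type for d in current]
        midx += 1
        role = "elongation+E" if "E" in types else "elongation"
        mod = ModuleArch(midx, current, role)
        if "C" not in types:
            mod.complete = False
            prev_end = 0
            if len(modules) >= 1 and modules[-1].domains:
                prev_end = modules[-1].domains[-1].end
            a_hits = [d for d in current if d.domain_type == "A"]
            a_start = a_hits[0].start if a_hits else (current[0].start if current else 0)
            # may be empty (hi < lo) when the flanking domains are contiguous
            mod.missing_c_interval = (prev_end + 1, a_start - 1)
        if "A" not in types:
            diagnostics.append(f"module M{midx} lacks an A domain")
        if "PCP" not in types:
            diagnostics.append(f"module M{midx} lacks a PCP domain")
        modules.append(mod)
        current = None

    while i < len(hits):
        h = hits[i]
        t = h.domain_type
        if t == "C":
            close_current()
            current = [h]
        elif t == "A":
            if current is None:
                current = [h]  # elongation module missing its C
            elif any(d.domain_type == "A" for d in current):
                close_current()
                current = [h]
            else:
                current.append(h)
        elif t == "PCP":
            if current is None:
                diagnostics.append(f"stray PCP at position {h.start} outside any module")
                current = [h]
            elif any(d.domain_type == "PCP" for d in current):
                close_current()
                diagnostics.append(f"unexpected extra PCP at position {h.start}")
                current = [h]
            else:
                current.append(h)
        elif t == "E":
            if current is None:
                diagnostics.append(f"stray E domain at position {h.start}")
            else:
                current.append(h)
        elif t == "CT":
            close_current()
            midx += 1
            modules.append(ModuleArch(midx, [h], "termination"))
        else:
            diagnostics.append(f"PKS-type domain {t} ignored by the NRPS grammar")
        i += 1
    close_current()
    return Architecture(modules, diagnostics)


# ---------------------------------------------------------------------------
# condensation-domain subtyping


@dataclass
class SubtypeCall:
    ranked: list[tuple[str, float]]
    margin: float
    ambiguous: bool
    unclassified: bool = False


def classify_cdomain(
    seq: str,
    subtype_profiles: Mapping[str, ProfileModel],
    ambiguity_margin: float = 1.0,
    n_shuffles: int = 0,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> SubtypeCall:
    """Score a condensation domain under each subtype profile.

    Returns subtypes ranked by best-window bit score with the top-two
    margin; calls with margin below ``ambiguity_margin`` are flagged
    ambiguous.  With ``n_shuffles`` > 0 the top call additionally gets a
    shuffle-based empirical p; above ``p_threshold`` the sequence is
    reported unclassified.
    """
    if not subtype_profiles or len(subtype_profiles) < 2:
        raise ValueError("need at least two subtype profiles")
    scored: list[tuple[str, float]] = []
    for name in sorted(subtype_profiles):
        prof = subtype_profiles[name]
        if len(seq) < prof.length:
            scored.append((name, -math.inf))
            continue
        hit = scan_profile(prof, seq, n_shuffles=0)
        scored.append((name, hit.score))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    margin = scored[0][1] - scored[1][1] if len(scored) > 1 else math.inf
    call = SubtypeCall(ranked=scored, margin=margin, ambiguous=margin < ambiguity_margin)
    if n_shuffles > 0:
        top = subtype_profiles[scored[0][0]]
        hit = scan_profile(top, seq, n_shuffles=n_shuffles, seed=seed)
        if hit.empirical_p is not None and hit.empirical_p > p_threshold:
            call.unclassified = True
    return call


# ---------------------------------------------------------------------------
# collinearity product prediction


class PredictionError(ValueError):
    """An A-domain code could not be resolved against the code table."""


@dataclass
class PredictedProduct:
    peptide: Peptide
    provenance: list[dict] = field(default_factory=list)

    @property
    def residues(self) -> tuple[Residue, ...]:
        return self.peptide.residues

    def structure_string(self) -> str:
        parts = []
        for res in self.peptide.residues:
            if res.chirality in ("L", "D"):
                parts.append(f"{res.chirality}-{res.name}")
            else:
                parts.append(res.name)
        inner = "-".join(parts)
        return f"cyclo-[{inner}]" if self.peptide.topology == "macrolactone" else inner


def predict_product(
    arch: Architecture,
    codes: Mapping[int, SpecificityCode | str],
    table: CodeTable,
    lipid: str = "HMHDA",
    max_distance: int = 2,
    isoform_map: Mapping[str, str] | None = None,
) -> PredictedProduct:
    """Collinearity-based product from a parsed architecture and A-domain codes.

    ``codes`` maps module index → extracted specificity code.  Each
    A-bearing module contributes one residue: exact table lookup first,
    then nearest-neighbour within ``max_distance`` Hamming steps.  Residues
    of E-bearing modules are D-configured, glycine is achiral, everything
    else is L.  An initiation PCP prepends the lipid; a terminal CT closes
    the macrolactone.  ``isoform_map`` substitutes mass-identical library
    isoforms (e.g. Thr → allo-Thr) when chromatographic evidence — which MS
    and the code table cannot supply — resolves them.
    """
    isoform_map = dict(isoform_map or {})
    specs: list[Residue] = []
    provenance: list[dict] = []
    has_ct = any(m.role == "termination" for m in arch.modules)
    for mod in arch.modules:
        if mod.role == "initiation":
            res = library_residue(lipid)
            specs.append(res)
            provenance.append({"module": mod.index, "residue": lipid, "source": "initiation PCP"})
            continue
        if mod.role == "termination":
            continue
        if not mod.has_A:
            raise PredictionError(f"module M{mod.index} has no A domain to read a code from")
        if mod.index not in codes:
            raise PredictionError(f"no specificity code supplied for module M{mod.index}")
        code = codes[mod.index]
        label = lookup_code(code, table)
        source = "exact code match"
        distance = 0
        if label is None:
            ranked = nearest_code(code, table, max_distance=max_distance)
            if not ranked:
                raise PredictionError(
                    f"module M{mod.index}: code {code} has no table hit within "
                    f"Hamming distance {max_distance}"
                )
            label, distance = ranked[0]
            source = f"nearest code (distance {distance})"
        label = isoform_map.get(label, label)
        base = library_residue(label)
        if base.chirality == "achiral":
            chirality = "achiral"
        else:
            chirality = "D" if mod.has_E else "L"
        specs.append(base.with_chirality(chirality))
        provenance.append(
            {
                "module": mod.index,
                "residue": label,
                "code": str(code),
                "has_E": mod.has_E,
                "source": source,
                "distance": distance,
            }
        )
    topology = "macrolactone" if has_ct else "linear"
    peptide = Peptide(tuple(specs), topology)
    n_d = sum(1 for r in peptide.residues if r.chirality == "D")
    n_e = sum(1 for m in arch.modules if m.has_E)
    assert n_d <= n_e, "more D residues than E-bearing modules"
    return PredictedProduct(peptide, provenance)
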