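"""Adenylation-domain specificity (Stachelhaus) code extraction and lookup.

The substrate selectivity of an NRPS adenylation domain is encoded by the
eight binding-pocket residues at GrsA-PheA reference positions 235, 236,
239, 278, 299, 301, 322 and 330 (C331 and K517 are excluded).  The code is
read by globally aligning a query A domain to a reference A domain and
taking the query letters in the columns of the eight reference positions.

Prediction is by exact lookup in a code table, falling back to
nearest-neighbour search under Hamming distance; the packaged table holds
the six codes characterised for the BIIRfg cluster (Ala, Glu, Asn, Ser,
Thr, Gly).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "GRSA_POCKET_POSITIONS",
    "ReferenceAnchor",
    "SpecificityCode",
    "CodeTable",
    "AlphabetError",
    "LowConfidenceError",
    "global_align",
    "extract_code",
    "lookup_code",
    "nearest_code",
]

#: The eight pocket positions in GrsA PheA numbering (1-based).
GRSA_POCKET_POSITIONS = (235, 236, 239, 278, 299, 301, 322, 330)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class AlphabetError(ValueError):
    """Sequence contains a character outside the amino-acid alphabet."""


class LowConfidenceError(ValueError):
    """Too many pocket positions aligned to gaps to trust the extraction."""


def _check_sequence(seq: str, what: str) -> str:
    if not seq:
        raise AlphabetError(f"{what}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise AlphabetError(f"{what}: invalid residue characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class ReferenceAnchor:
    """A reference A-domain sequence with its pocket positions (1-based)."""

    sequence: str
    pocket_positions: tuple[int, ...] = GRSA_POCKET_POSITIONS
    label: str = "reference A domain"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "anchor"))
        object.__setattr__(self, "pocket_positions", tuple(self.pocket_positions))
        pos = self.pocket_positions
        if list(pos) != sorted(set(pos)):
            raise ValueError("pocket positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > len(self.sequence):
            raise ValueError("pocket positions outside the reference sequence")

    def pocket_letters(self) -> str:
        return "".join(self.sequence[p - 1] for p in self.pocket_positions)


@dataclass(frozen=True)
class SpecificityCode:
    code: str
    source_positions: tuple[int | None, ...] = ()

    def __post_init__(self) -> None:
        if len(self.code) != 8:
            raise ValueError(f"specificity code must be 8 characters, got {self.code!r}")
        if set(self.code) - (AA_ALPHABET | {"-"}):
            raise ValueError(f"invalid characters in code {self.code!r}")

    @property
    def gapped(self) -> bool:
        return "-" in self.code

    def __str__(self) -> str:
        return self.code


@dataclass
class CodeTable:
    """Rows of (8-letter code, amino-acid label, provenance)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for code, label, _prov in self.entries:
            if len(code) != 8:
                raise ValueError(f"code {code!r} is not 8 characters")
            if code in seen and seen[code] != label:
                raise ValueError(f"duplicate code {code!r} with conflicting labels")
            seen[code] = label

    @classmethod
    def packaged(cls) -> "CodeTable":
        """The six BIIRfg cluster codes shipped with the package."""
        text = resources.files("nrpsmine.data").joinpath("stachelhaus_codes.tsv").read_text()
        return cls.from_tsv_text(text)

    @classmethod
    def from_tsv_text(cls, text: str) -> "CodeTable":
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
        return cls([(r["code"], r["amino_acid"], r.get("provenance", "")) for r in rows])

    @classmethod
    def from_tsv(cls, path: str) -> "CodeTable":
        with open(path) as fh:
            return cls.from_tsv_text(fh.read())

    def without(self, label: str) -> "CodeTable":
        return CodeTable([e for e in self.entries if e[1] != label])


def _aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    query: str,
    ref: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str, float]:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment.

    Returns (gapped query, gapped reference, score).  Among co-optimal
    alignments the first in the aligner's deterministic enumeration is
    taken, so results are reproducible for fixed parameters.
    """
    query = _check_sequence(query, "query")
    ref = _check_sequence(ref, "reference")
    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(query, ref)[0]
    gq, gr = str(aln[0]), str(aln[1])
    return gq, gr, float(aln.score)


def extract_code(
    query: str,
    anchor: ReferenceAnchor,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    max_gapped_positions: int = 4,
) -> SpecificityCode:
    """Read the query's pocket letters through alignment to the anchor.

    A reference pocket position whose alignment column holds a query gap
    contributes '-'; if more than ``max_gapped_positions`` of the eight do,
    the alignment is unusable and :class:`LowConfidenceError` is raised.
    """
    gq, gr, _score = global_align(query, anchor.sequence, matrix, gap_open, gap_extend)
    # map each reference position (1-based, ungapped) to its column
    ref_col: dict[int, int] = {}
    rpos = 0
    for col, ch in enumerate(gr):
        if ch != "-":
            rpos += 1
            ref_col[rpos] = col
    letters: list[str] = []
    source: list[int | None] = []
    qpos_at_col: list[int] = []
    qpos = 0
    for ch in gq:
        if ch != "-":
            qpos += 1
        qpos_at_col.append(qpos)
    for p in anchor.pocket_positions:
        col = ref_col[p]
        ch = gq[col]
        if ch == "-":
            letters.append("-")
            source.append(None)
        else:
            letters.append(ch)
            source.append(qpos_at_col[col])
    code = "".join(letters)
    n_gaps = code.count("-")
    if n_gaps > max_gapped_positions:
        raise LowConfidenceError(
            f"{n_gaps} of 8 pocket positions aligned to gaps; alignment unusable"
        )
    return SpecificityCode(code, tuple(source))


def lookup_code(c: SpecificityCode | str, table: CodeTable) -> str | None:
    """Exact code-table lookup; None if absent."""
    if not table.entries:
        raise ValueError("code table is empty")
    code = str(c)
    for entry_code, label, _prov in table.entries:
        if entry_code == code:
            return label
    return None


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("codes must have equal length")
    return int(np.sum(np.frombuffer(a.encode(), dtype=np.uint8) != np.frombuffer(b.encode(), dtype=np.uint8)))


def nearest_code(
    c: SpecificityCode | str,
    table: CodeTable,
    max_distance: int = 8,
) -> list[tuple[str, int]]:
    """Labels ranked by Hamming distance (ascending; ties alphabetically)."""
    code = c if isinstance(c, SpecificityCode) else SpecificityCode(str(c))
    if code.gapped:
        raise ValueError("nearest-neighbour search is unsupported for gapped codes")
    best: dict[str, int] = {}
    for entry_code, label, _prov in table.entries:
        d = hamming(code.code, entry_code)
        if d <= max_distance and (label not in best or d < best[label]):
            best[label] = d
    return sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
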