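"""b/y fragment-ion ladders for linear lipopeptides and ladder sequencing.

Only singly protonated b and y ions are modeled.  A b_i ion is the N-terminal
acylium-equivalent cation (Σ residues 1..i plus one proton); a y_j ion keeps
the C-terminal water (Σ residues n−j+1..n plus H2O plus one proton).  The
complementarity identity mz(b_i) + mz(y_{n−i}) = mz([M+H]+) + mz(H+) holds
exactly under this accounting.

`infer_losses` reconstructs the residue-loss order by walking the descending
b-ladder from the protonated parent: the first step (parent → largest b ion)
loses one residue plus water, every later step loses one residue.  Residues
that are isobaric within tolerance (Thr / allo-Thr / homoserine) are reported
as an ambiguity set; the returned code follows library insertion order, and
LC-based stereochemistry (Marfey) — not MS — is the arbiter between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import ELECTRON_MASS, PROTON, WATER, IonSpec, MolecularFormula, ion_mz, monoisotopic_mass, ppm_error
from .residues import Peptide, Residue, TopologyError

__all__ = [
    "FragmentIon",
    "Peak",
    "PeakList",
    "LadderMatch",
    "AmbiguityError",
    "predict_ladder",
    "match_peaks",
    "infer_losses",
]

PROTON_MZ = monoisotopic_mass(PROTON) - ELECTRON_MASS
WATER_MASS = monoisotopic_mass(WATER)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int
    formula: MolecularFormula  # singly protonated cation
    mz: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass
class PeakList:
    peaks: list[Peak]
    parent_mz: float | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]


@dataclass
class LadderMatch:
    assignments: list[tuple[Peak, FragmentIon, float]] = field(default_factory=list)
    unassigned: list[Peak] = field(default_factory=list)
    residue_loss_sequence: list[str] = field(default_factory=list)


class AmbiguityError(ValueError):
    """A ladder step matched no residue, or several non-isobaric residues."""


def predict_ladder(p: Peptide) -> list[FragmentIon]:
    """Singly charged b1..b(n-1) and y1..y(n-1) ions of a linear peptide."""
    if p.topology != "linear":
        raise TopologyError("fragment ladders are predicted for linear peptides; hydrolyze first")
    if len(p) < 2:
        raise ValueError("need at least 2 residues for a fragment ladder")
    n = len(p)
    ions: list[FragmentIon] = []
    acc = MolecularFormula()
    for i, res in enumerate(p.residues[:-1], start=1):
        acc = acc + res.residue_formula
        f = acc + PROTON
        ions.append(FragmentIon("b", i, f, ion_mz(IonSpec(f, 1))))
    acc = MolecularFormula()
    for j, res in enumerate(reversed(p.residues[1:]), start=1):
        acc = acc + res.residue_formula
        f = acc + WATER + PROTON
        ions.append(FragmentIon("y", j, f, ion_mz(IonSpec(f, 1))))
    return ions


def match_peaks(obs: PeakList, predicted: list[FragmentIon], tol_ppm: float = 5.0) -> LadderMatch:
    """Greedy nearest matching of observed peaks to predicted fragments.

    Candidate (fragment, peak) pairs within ``tol_ppm`` are assigned in order
    of increasing |ppm error| (ties: b before y, then lower index); each peak
    and each fragment is used at most once.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not predicted:
        raise ValueError("empty prediction list")
    candidates = []
    for frag in predicted:
        for k, peak in enumerate(obs.peaks):
            err = ppm_error(peak.mz, frag.mz)
            if abs(err) <= tol_ppm:
                candidates.append((abs(err), 0 if frag.series == "b" else 1, frag.index, k, peak, frag, err))
    candidates.sort(key=lambda c: c[:4])
    used_peaks: set[int] = set()
    used_frags: set[str] = set()
    match = LadderMatch()
    for _, _, _, k, peak, frag, err in candidates:
        if k in used_peaks or frag.label in used_frags:
            continue
        used_peaks.add(k)
        used_frags.add(frag.label)
        match.assignments.append((peak, frag, err))
    match.unassigned = [p for k, p in enumerate(obs.peaks) if k not in used_peaks]
    match.assignments.sort(key=lambda a: a[0].mz)
    return match


def _step_residue(
    delta: float, library: list[Residue], tol: float
) -> tuple[Residue, list[str]]:
    """Match a mass difference to a unique residue mass; isobaric residues
    collapse to one ambiguity set, distinct masses within tol are an error."""
    hits = [r for r in library if abs(r.mass - delta) <= tol]
    if not hits:
        raise AmbiguityError(f"ladder step of {delta:.4f} Da matches no library residue")
    masses = {round(r.mass, 4) for r in hits}
    if len(masses) > 1:
        names = ", ".join(r.name for r in hits)
        raise AmbiguityError(f"ladder step of {delta:.4f} Da is ambiguous between {names}")
    return hits[0], [r.name for r in hits]


def infer_losses(
    obs: PeakList,
    library: list[Residue] | dict[str, Residue],
    parent_mz: float | None = None,
    tol: float = 0.01,
    skip_unmatched: bool = False,
) -> list[str]:
    """Residue-loss order from a descending b-ion ladder.

    Walks from the protonated parent down through the observed peaks: the
    first step corresponds to loss of (residue + H2O), every later step to
    loss of one residue.  In strict mode (default) a step whose mass
    difference matches no library residue raises :class:`AmbiguityError`
    reporting the step mass; with ``skip_unmatched=True`` such peaks are
    treated as decoys and skipped, which is the right setting for raw
    instrument peak lists.  Returns residue codes in loss order.
    """
    if isinstance(library, dict):
        library = list(library.values())
    if not library:
        raise ValueError("residue library is empty")
    parent = parent_mz if parent_mz is not None else obs.parent_mz
    if parent is None:
        raise ValueError("parent m/z required (argument or PeakList.parent_mz)")
    mzs = sorted(obs.mzs(), reverse=True)

    if not skip_unmatched:
        # strict sequential walk: every peak below the current position must
        # continue the ladder, otherwise the step mass is reported
        losses: list[str] = []
        current = parent
        first = True
        while True:
            offset = WATER_MASS if first else 0.0
            below = [mz for mz in mzs if mz < current - 1e-9]
            if not below:
                break
            delta = current - below[0] - offset
            hits = [r for r in library if abs(r.mass - delta) <= tol]
            if not hits:
                raise AmbiguityError(
                    f"ladder step of {delta:.4f} Da (to peak {below[0]:.4f}) "
                    "matches no library residue"
                )
            residue, _ambig = _step_residue(delta, library, tol)
            losses.append(residue.name)
            current = below[0]
            first = False
        return losses

    # decoy-tolerant walk: among all residue-sized step chains down from the
    # parent, take the longest (decoy branches dead-end quickly); equal-length
    # chains are ranked by smaller cumulative |mass residual|, which separates
    # true ladder peaks (instrument-accuracy residuals) from decoys that only
    # just fall inside the tolerance window
    from functools import lru_cache

    n = len(mzs)

    def residue_for(delta: float) -> tuple[Residue, float] | None:
        hits = [r for r in library if abs(r.mass - delta) <= tol]
        if not hits:
            return None
        res = _step_residue(delta, library, tol)[0]
        return res, abs(res.mass - delta)

    @lru_cache(maxsize=None)
    def best_chain(i: int) -> tuple[int, float, tuple[str, ...]]:
        best: tuple[int, float, tuple[str, ...]] = (0, 0.0, ())
        for j in range(i + 1, n):
            match = residue_for(mzs[i] - mzs[j])
            if match is None:
                continue
            res, residual = match
            length, tail_residual, tail = best_chain(j)
            cand = (length + 1, residual + tail_residual, (res.name,) + tail)
            if (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
        return best

    overall: tuple[int, float, tuple[str, ...]] = (0, 0.0, ())
    for i in range(n):
        if mzs[i] >= parent - 1e-9:
            continue
        match = residue_for(parent - mzs[i] - WATER_MASS)
        if match is None:
            continue
        res, residual = match
        length, tail_residual, tail = best_chain(i)
        cand = (length + 1, residual + tail_residual, (res.name,) + tail)
        if (cand[0], -cand[1]) > (overall[0], -overall[1]):
            overall = cand
    return list(overall[2])
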