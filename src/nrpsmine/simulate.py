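"""Deterministic synthetic-data generators for every pipeline input.

The generators emulate the study system — a fungal lipodepsipeptide
NRPS — well enough to exercise each stage with known ground truth:

* ``make_reference``: a surrogate reference A domain (~550 aa) carrying the
  ten adenylation core motifs mA1–mA10 in order, with eight designated
  binding-pocket positions in the region between mA4 and mA5.
* ``make_cluster``: a multi-module NRPS protein assembled from the domain
  grammar, whose A domains are mutated copies of the reference with a
  chosen specificity code planted at the pocket positions (indels are kept
  out of the ±5-column pocket neighbourhoods so extraction stays
  well-posed), C domains carry HHxxxDG, E domains HHxxxDxVSW.
* ``make_ms2``: the b/y ladder of the (hydrolysed) product with uniform
  ppm jitter and optional uniform decoy peaks.
* ``make_marfey``: one chromatogram peak per chiral analyte at the
  standard's retention time ± jitter, areas proportional to multiplicity,
  Asn emitted as Asp (acid hydrolysis).

Every generator is a pure function of (spec, seed); each draws from its own
named substream of the seed so adding one generator never shifts another's
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import PROTON, IonSpec, ion_mz
from .cluster import Architecture, DomainHit, PredictedProduct, parse_architecture
from .fragments import Peak, PeakList, predict_ladder
from .marfey import HYDROLYSIS_MAP, StandardsTable
from .residues import Peptide, library_residue
from .specificity import CodeTable, ReferenceAnchor

__all__ = [
    "SyntheticClusterSpec",
    "GroundTruth",
    "make_reference",
    "make_cluster",
    "make_ms2",
    "make_marfey",
    "random_cluster_spec",
    "biirfg_shaped_spec",
    "BIIRFG_SHAPED_SPEC",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# residues with pairwise-distinct monoisotopic masses, so ladder walking is
# unambiguous on generator output (drops Ile, allo-Thr, Homoser isobars)
MASS_DISTINCT_POOL = (
    "Gly", "Ala", "Ser", "Pro", "Val", "Thr", "Cys", "Leu", "Asn", "Asp",
    "Gln", "Lys", "Glu", "Met", "His", "Phe", "Arg", "Tyr", "Trp",
)

_STREAMS = {"reference": 1, "cluster": 2, "ms2": 3, "marfey": 4, "spec": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for ch in pattern:
        if ch == "x" or ch.islower():
            out.append(AA20[rng.integers(20)])
        else:
            out.append(ch)
    return "".join(out)


_MOTIF_ORDER = [
    ("mA1", "LTYxEL"),
    ("mA2", "LKAGxAYVPID"),
    ("mA3", "LAYxxYTSGTTGxPKG"),
    ("mA4", "FdxS"),
    ("mA5", "NxYGPTE"),
    ("mA6", "GELxIxGxGLARGYW"),
    ("mA7", "YKTGDQ"),
    ("mA8", "GrxDxQVKIRGxRVELEEVE"),
    ("mA9", "LpxYMIP"),
    ("mA10", "NGKIDR"),
]


def make_reference(seed: int = 0) -> ReferenceAnchor:
    """Surrogate reference A domain with mA1–mA10 in order and eight pocket
    positions spread through the mA4–mA5 inter-motif region."""
    rng = _rng(seed, "reference")
    parts: list[str] = [_random_aa(rng, int(rng.integers(20, 35)))]
    pocket_positions: list[int] = []
    for name, pattern in _MOTIF_ORDER:
        parts.append(_instantiate(pattern, rng))
        if name == "mA4":
            # ~100-residue specificity region hosting the eight pocket columns
            region_len = 100
            offsets = np.sort(rng.choice(np.arange(5, region_len - 5), size=8, replace=False))
            base = sum(len(p) for p in parts)
            region = list(_random_aa(rng, region_len))
            pocket_positions = [int(base + o + 1) for o in offsets]
            parts.append("".join(region))
        elif name != "mA10":
            parts.append(_random_aa(rng, int(rng.integers(25, 45))))
    parts.append(_random_aa(rng, int(rng.integers(20, 40))))
    seq = "".join(parts)
    return ReferenceAnchor(seq, tuple(pocket_positions), label=f"synthetic reference (seed {seed})")


@dataclass
class SyntheticClusterSpec:
    """Recipe for a synthetic NRPS protein with known ground truth."""

    modules: list[tuple[str, bool]]  # (residue code, has_E)
    codes: list[str]  # 8-letter specificity code per module
    include_initiation_pcp: bool = True
    include_ct: bool = True
    substitution_rate: float = 0.05
    indel_rate: float = 0.02
    pocket_guard: int = 5  # no indels within ± this many columns of a pocket
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.modules):
            raise ValueError("one specificity code required per module")
        for code in self.codes:
            if len(code) != 8 or set(code) - set(AA20):
                raise ValueError(f"bad specificity code {code!r}")
        for res, _ in self.modules:
            library_residue(res)  # raises on unknown code


@dataclass
class GroundTruth:
    domain_hits: list[DomainHit]
    codes: dict[int, str]  # architecture module index -> planted code
    code_table: CodeTable
    product: PredictedProduct
    ladder: list
    marfey_rows: list[tuple[float, float]]
    marfey_analytes: list[str]

    @property
    def architecture(self) -> Architecture:
        return parse_architecture(self.domain_hits)


def _mutate_adomain(
    anchor: ReferenceAnchor,
    code: str,
    rng: np.random.Generator,
    sub_rate: float,
    indel_rate: float,
    guard: int,
) -> str:
    pockets = set(anchor.pocket_positions)
    guarded = set()
    for p in anchor.pocket_positions:
        guarded.update(range(p - guard, p + guard + 1))
    pocket_letter = {p: code[i] for i, p in enumerate(anchor.pocket_positions)}
    out: list[str] = []
    for pos1, ch in enumerate(anchor.sequence, start=1):
        if pos1 in pockets:
            out.append(pocket_letter[pos1])
            continue
        if pos1 not in guarded and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(AA20[rng.integers(20)])  # insertion before the column
        if rng.random() < sub_rate:
            out.append(AA20[rng.integers(20)])
        else:
            out.append(ch)
    return "".join(out)


def _cdomain(rng: np.random.Generator, motif: str = "HHxxxDG") -> str:
    body = list(_random_aa(rng, 120))
    inst = _instantiate(motif, rng)
    at = int(rng.integers(20, 60))
    return "".join(body[:at]) + inst + "".join(body[at:])


def _edomain(rng: np.random.Generator) -> str:
    body = list(_random_aa(rng, 100))
    inst = _instantiate("HHxxxDxVSW", rng)
    at = int(rng.integers(15, 50))
    return "".join(body[:at]) + inst + "".join(body[at:])


def _pcp(rng: np.random.Generator) -> str:
    return _random_aa(rng, int(rng.integers(70, 90)))


def _truth_product(spec: SyntheticClusterSpec) -> PredictedProduct:
    residues = []
    provenance = []
    if spec.include_initiation_pcp:
        residues.append(library_residue("HMHDA"))
        provenance.append({"module": 1, "residue": "HMHDA", "source": "ground truth"})
    offset = 1 if spec.include_initiation_pcp else 0
    for k, (code_name, has_e) in enumerate(spec.modules):
        base = library_residue(code_name)
        chirality = "achiral" if base.chirality == "achiral" else ("D" if has_e else "L")
        residues.append(base.with_chirality(chirality))
        provenance.append(
            {"module": offset + k + 1, "residue": code_name, "has_E": has_e, "source": "ground truth"}
        )
    topology = "macrolactone" if spec.include_ct and spec.include_initiation_pcp else "linear"
    return PredictedProduct(Peptide(tuple(residues), topology), provenance)


def make_cluster(
    spec: SyntheticClusterSpec, anchor: ReferenceAnchor
) -> tuple[str, GroundTruth]:
    """Assemble the synthetic NRPS protein and its ground truth."""
    rng = _rng(spec.seed, "cluster")
    pieces: list[tuple[str, str]] = []  # (domain type, sequence)
    if spec.include_initiation_pcp:
        pieces.append(("PCP", _pcp(rng)))
    for (res, has_e), code in zip(spec.modules, spec.codes):
        pieces.append(("C", _cdomain(rng)))
        pieces.append(
            ("A", _mutate_adomain(anchor, code, rng, spec.substitution_rate, spec.indel_rate, spec.pocket_guard))
        )
        pieces.append(("PCP", _pcp(rng)))
        if has_e:
            pieces.append(("E", _edomain(rng)))
    if spec.include_ct:
        pieces.append(("CT", _cdomain(rng, motif="SHxxxDG")))

    seq_parts: list[str] = []
    hits: list[DomainHit] = []
    pos = 0
    for dtype, dseq in pieces:
        start = pos + 1
        pos += len(dseq)
        seq_parts.append(dseq)
        hits.append(DomainHit(dtype, start, pos, evidence=("synthetic",)))
    protein = "".join(seq_parts)

    offset = 1 if spec.include_initiation_pcp else 0
    codes = {offset + k + 1: code for k, code in enumerate(spec.codes)}
    table_rows = []
    seen: dict[str, str] = {}
    for (res, _), code in zip(spec.modules, spec.codes):
        if code in seen and seen[code] != res:
            raise ValueError(f"code {code} planted for two different residues")
        seen[code] = res
        table_rows.append((code, res, "synthetic"))
    product = _truth_product(spec)
    linear = Peptide(product.peptide.residues, "linear")
    ladder = predict_ladder(linear) if len(linear) >= 2 else []
    marfey_rows, analytes = _marfey_truth(product)
    return protein, GroundTruth(
        domain_hits=hits,
        codes=codes,
        code_table=CodeTable(table_rows),
        product=product,
        ladder=ladder,
        marfey_rows=marfey_rows,
        marfey_analytes=analytes,
    )


def _marfey_truth(
    product: PredictedProduct, standards: StandardsTable | None = None
) -> tuple[list[tuple[float, float]], list[str]]:
    standards = standards or StandardsTable.packaged()
    counts: dict[str, int] = {}
    for res in product.peptide.residues:
        if res.kind == "lipid":
            continue
        name = HYDROLYSIS_MAP.get(res.name, res.name)
        if res.chirality in ("L", "D"):
            label = f"{res.chirality}-{name}"
        else:
            label = name
        counts[label] = counts.get(label, 0) + 1
    rows: list[tuple[float, float]] = []
    analytes: list[str] = []
    for label, mult in counts.items():
        try:
            rt = standards.rt(label)
        except KeyError:
            continue  # no derivatized standard for this analyte
        rows.append((rt, 1.0e6 * mult))
        analytes.append(label)
    return rows, analytes


def make_ms2(
    product: PredictedProduct,
    ppm_jitter: float = 3.0,
    n_decoys: int = 0,
    seed: int = 0,
) -> PeakList:
    """Observed-like MS2 peak list for the (hydrolysed) product."""
    rng = _rng(seed, "ms2")
    peptide = product.peptide
    if peptide.topology == "macrolactone":
        peptide = Peptide(peptide.residues, "linear")
    ladder = predict_ladder(peptide)
    parent = ion_mz(IonSpec(peptide.formula + PROTON, 1))

    def jitter(mz: float) -> float:
        if ppm_jitter <= 0:
            return mz
        return mz * (1.0 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)

    peaks = [Peak(jitter(f.mz), float(rng.uniform(1e4, 1e6))) for f in ladder]
    lo = min(f.mz for f in ladder) * 0.5
    for _ in range(n_decoys):
        peaks.append(Peak(float(rng.uniform(lo, parent * 0.98)), float(rng.uniform(1e3, 1e5))))
    return PeakList(peaks, parent_mz=jitter(parent))


def make_marfey(
    product: PredictedProduct,
    rt_jitter: float = 0.0,
    seed: int = 0,
    standards: StandardsTable | None = None,
) -> list[tuple[float, float]]:
    """Chromatogram rows (rt, area) for the product's chiral analytes."""
    rng = _rng(seed, "marfey")
    rows, _ = _marfey_truth(product, standards)
    out = []
    for rt, area in rows:
        jit = float(rng.uniform(-rt_jitter, rt_jitter)) if rt_jitter > 0 else 0.0
        out.append((rt + jit, area))
    return out


def biirfg_shaped_spec(seed: int = 0) -> SyntheticClusterSpec:
    """The architecture of the study cluster: initiation PCP, eight
    elongation modules with E domains on modules M7 and M8 (the third Ser
    and the Thr), terminal CT.  Codes are the six characterised specificity
    codes, the serine code shared by three modules per the cluster's own
    A4/A5/A6 identity."""
    return SyntheticClusterSpec(
        modules=[
            ("Ala", False),
            ("Glu", False),
            ("Asn", False),
            ("Ser", False),
            ("Ser", False),
            ("Ser", True),
            ("Thr", True),
            ("Gly", False),
        ],
        codes=[
            "DVATITAI",
            "DVTHSGSV",
            "DVSNVGSI",
            "DVQTVMAI",
            "DVQTVMAI",
            "DVQTVMAI",
            "DAQTIMAI",
            "DVSNVIGI",
        ],
        include_initiation_pcp=True,
        include_ct=True,
        seed=seed,
    )


BIIRFG_SHAPED_SPEC = biirfg_shaped_spec()


def random_cluster_spec(
    seed: int,
    n_modules: tuple[int, int] = (3, 8),
    p_epimerize: float = 0.3,
) -> SyntheticClusterSpec:
    """A random cluster over mass-distinct residues with unique random codes."""
    rng = _rng(seed, "spec")
    n = int(rng.integers(n_modules[0], n_modules[1] + 1))
    residues = [str(rng.choice(MASS_DISTINCT_POOL)) for _ in range(n)]
    codes: dict[str, str] = {}
    used: set[str] = set()
    for res in set(residues):
        while True:
            code = "".join(rng.choice(list(AA20), size=8))
            if code not in used:
                used.add(code)
                codes[res] = code
                break
    modules = [(res, bool(rng.random() < p_epimerize)) for res in residues]
    return SyntheticClusterSpec(
        modules=modules,
        codes=[codes[res] for res, _ in modules],
        include_initiation_pcp=True,
        include_ct=True,
        seed=seed,
    )
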