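"""Convenience drivers chaining the mining stages end to end."""

from __future__ import annotations

from typing import Mapping, Sequence

from .cluster import Architecture, DomainHit, PredictedProduct, parse_architecture, predict_product
from .specificity import CodeTable, ReferenceAnchor, SpecificityCode, extract_code

__all__ = ["extract_module_codes", "mine_cluster"]


def extract_module_codes(
    protein: str, arch: Architecture, anchor: ReferenceAnchor
) -> dict[int, SpecificityCode]:
    """Specificity codes for every A-bearing module, read from the protein."""
    codes: dict[int, SpecificityCode] = {}
    for mod in arch.modules:
        if not mod.has_A:
            continue
        a_hit = next(d for d in mod.domains if d.domain_type == "A")
        codes[mod.index] = extract_code(protein[a_hit.start - 1 : a_hit.end], anchor)
    return codes


def mine_cluster(
    protein: str,
    hits: Sequence[DomainHit],
    anchor: ReferenceAnchor,
    table: CodeTable,
    isoform_map: Mapping[str, str] | None = None,
) -> tuple[Architecture, dict[int, SpecificityCode], PredictedProduct]:
    """Architecture parse → code extraction → collinearity product."""
    arch = parse_architecture(hits)
    codes = extract_module_codes(protein, arch, anchor)
    product = predict_product(arch, codes, table, isoform_map=isoform_map)
    return arch, codes, product
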