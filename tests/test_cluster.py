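import numpy as np
import pytest

from nrpsmine.cluster import (
    DomainHit,
    MotifSet,
    PredictionError,
    build_profile,
    classify_cdomain,
    parse_architecture,
    predict_product,
    scan_motifs,
    scan_profile,
)
from nrpsmine.specificity import CodeTable
from .conftest import _hits

AA = "ACDEFGHIKLMNPQRSTVWY"

BIIRFG_CODES = {
    2: "DVATITAI",
    3: "DVTHSGSV",
    4: "DVSNVGSI",
    5: "DVQTVMAI",
    6: "DVQTVMAI",
    7: "DVQTVMAI",
    8: "DAQTIMAI",
    9: "DVSNVIGI",
}


# --- motif scanning --------------------------------------------------------


def test_condensation_motif_found_at_correct_position():
    hits = scan_motifs("AAHHILMDGAA")
    c_hits = [h for h in hits if h.name == "C"]
    assert len(c_hits) == 1
    assert c_hits[0].position == 3
    assert c_hits[0].matched == "HHILMDG"


def test_variant_condensation_motif_is_flagged_non_canonical():
    hits = scan_motifs("XSHILMDGX".replace("X", "A"))
    variant = [h for h in hits if h.name == "C-variant-SHG"]
    assert len(variant) == 1
    assert not variant[0].canonical


def test_no_match_in_plain_sequence():
    assert [h for h in scan_motifs("AAAA") if h.name == "C"] == []


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        scan_motifs("")


def test_epimerization_motif_detection():
    seq = "M" * 10 + "HHQRTDAVSW" + "M" * 10
    assert any(h.name == "E" and h.position == 11 for h in scan_motifs(seq))


# --- profiles --------------------------------------------------------------


def _variants(consensus, n, rate, rng):
    out = []
    for _ in range(n):
        out.append(
            "".join(c if rng.random() > rate else AA[rng.integers(20)] for c in consensus)
        )
    return out


def test_profile_of_identical_sequences_peaks_at_their_letters():
    prof = build_profile(["ACDEF", "ACDEF"])
    assert prof.consensus() == "ACDEF"


def test_majority_gap_columns_are_dropped():
    prof = build_profile(["AC-EF", "AC-EF", "ACDEF"])
    assert prof.length == 4


def test_ragged_alignment_is_rejected():
    with pytest.raises(ValueError):
        build_profile(["ACDEF", "ACD"])


def test_profile_recovers_generator_consensus():
    rng = np.random.default_rng(5)
    consensus = "".join(rng.choice(list(AA), size=60))
    prof = build_profile(_variants(consensus, 8, 0.15, rng))
    assert sum(a == b for a, b in zip(prof.consensus(), consensus)) >= 55


def test_scan_profile_finds_embedded_training_sequence():
    rng = np.random.default_rng(6)
    consensus = "".join(rng.choice(list(AA), size=60))
    train = _variants(consensus, 8, 0.15, rng)
    prof = build_profile(train)
    flank = lambda n: "".join(rng.choice(list(AA), size=n))
    target = flank(80) + train[0] + flank(80)
    hit = scan_profile(prof, target, n_shuffles=1000, seed=1)
    assert hit.start == 81 and hit.end == 140
    assert hit.empirical_p <= 1 / 1001 + 1e-12


def test_scan_profile_null_targets_are_not_significant():
    rng = np.random.default_rng(7)
    consensus = "".join(rng.choice(list(AA), size=40))
    prof = build_profile(_variants(consensus, 6, 0.15, rng))
    target = "".join(rng.choice(list(AA), size=200))
    hit = scan_profile(prof, target, n_shuffles=1000, seed=2)
    assert hit.empirical_p >= 0.05


def test_consensus_self_scan_scores_the_column_maxima():
    prof = build_profile(["ACDEF", "ACDFF", "ACDEF"])
    hit = scan_profile(prof, prof.consensus(), n_shuffles=0)
    assert hit.score == pytest.approx(prof.max_score())


def test_scan_profile_rejects_short_targets():
    prof = build_profile(["ACDEF", "ACDEF"])
    with pytest.raises(ValueError):
        scan_profile(prof, "ACD")


# --- module grammar --------------------------------------------------------


def test_published_listing_parses_to_ten_modules_with_m9_incomplete(nrps_hits):
    arch = parse_architecture(nrps_hits)
    assert arch.n_modules == 10
    assert arch.n_domains == 27
    incomplete = arch.incomplete_modules()
    assert len(incomplete) == 1
    assert incomplete[0].index == 9
    # search interval spans the gap after the previous module's last domain
    lo, hi = incomplete[0].missing_c_interval
    a_start = next(d for d in incomplete[0].domains if d.domain_type == "A").start
    prev_end = arch.modules[7].domains[-1].end
    assert (lo, hi) == (prev_end + 1, a_start - 1)


def test_inserting_the_recovered_c_domain_completes_the_grammar(nrps_hits_complete):
    arch = parse_architecture(nrps_hits_complete)
    assert arch.n_modules == 10
    assert arch.n_domains == 28
    assert arch.incomplete_modules() == []
    roles = [m.role for m in arch.modules]
    assert roles[0] == "initiation"
    assert roles[-1] == "termination"
    assert roles[6] == roles[7] == "elongation+E"


def test_empty_hit_list_yields_empty_architecture_with_diagnostic():
    arch = parse_architecture([])
    assert arch.modules == []
    assert arch.diagnostics


def test_parser_is_total_on_out_of_order_domains():
    arch = parse_architecture(_hits(["E", "PCP", "A", "C"]))
    assert arch.diagnostics  # diagnostics, never exceptions


def test_parser_is_idempotent(nrps_hits):
    a1 = parse_architecture(nrps_hits)
    a2 = parse_architecture(nrps_hits)
    assert a1.summary() == a2.summary()
    assert a1.diagnostics == a2.diagnostics


# --- condensation subtyping ------------------------------------------------


def test_sampled_subtype_ranks_first():
    rng = np.random.default_rng(8)
    cons_a = "".join(rng.choice(list(AA), size=50))
    cons_b = "".join(rng.choice(list(AA), size=50))
    profiles = {
        "DCL": build_profile(_variants(cons_a, 6, 0.1, rng)),
        "LCL": build_profile(_variants(cons_b, 6, 0.1, rng)),
    }
    sample = _variants(cons_a, 1, 0.1, rng)[0]
    call = classify_cdomain(sample, profiles)
    assert call.ranked[0][0] == "DCL"
    assert not call.ambiguous


def test_equidistant_sequence_is_flagged_ambiguous():
    prof = build_profile(["ACDEF", "ACDEF"])
    profiles = {"x": prof, "y": prof}
    call = classify_cdomain("ACDEF", profiles)
    assert call.margin == pytest.approx(0.0)
    assert call.ambiguous


def test_classification_requires_two_profiles():
    prof = build_profile(["ACDEF", "ACDEF"])
    with pytest.raises(ValueError):
        classify_cdomain("ACDEF", {"only": prof})


# --- collinearity product prediction ---------------------------------------


def test_biirfg_architecture_predicts_the_established_structure(nrps_hits_complete):
    arch = parse_architecture(nrps_hits_complete)
    product = predict_product(
        arch, BIIRFG_CODES, CodeTable.packaged(), isoform_map={"Thr": "allo-Thr"}
    )
    assert (
        product.structure_string()
        == "cyclo-[HMHDA-L-Ala-L-Glu-L-Asn-L-Ser-L-Ser-D-Ser-D-allo-Thr-Gly]"
    )
    sers = [r for r in product.residues if r.name == "Ser"]
    assert sorted(r.chirality for r in sers) == ["D", "L", "L"]  # 2:1 L:D


def test_architecture_without_ct_gives_linear_product(nrps_hits_complete):
    arch = parse_architecture(nrps_hits_complete[:-1])
    product = predict_product(arch, BIIRFG_CODES, CodeTable.packaged())
    assert product.peptide.topology == "linear"


def test_d_residue_count_equals_e_bearing_module_count(nrps_hits_complete):
    arch = parse_architecture(nrps_hits_complete)
    product = predict_product(arch, BIIRFG_CODES, CodeTable.packaged())
    n_d = sum(1 for r in product.residues if r.chirality == "D")
    n_e = sum(1 for m in arch.modules if m.has_E)
    assert n_d == n_e == 2


def test_nearest_neighbour_fallback_is_recorded_in_provenance(nrps_hits_complete):
    arch = parse_architecture(nrps_hits_complete)
    table = CodeTable.packaged().without("Thr")
    product = predict_product(arch, BIIRFG_CODES, table)
    thr_entry = next(p for p in product.provenance if p.get("code") == "DAQTIMAI")
    assert thr_entry["residue"] == "Ser"  # nearest at distance 2
    assert thr_entry["distance"] == 2


def test_unresolvable_code_names_the_module(nrps_hits_complete):
    arch = parse_architecture(nrps_hits_complete)
    codes = {**BIIRFG_CODES, 5: "WWWWWWWW"}
    with pytest.raises(PredictionError, match="M5"):
        predict_product(arch, codes, CodeTable.packaged())
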