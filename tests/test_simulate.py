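import numpy as np
import pytest

from nrpsmine.fragments import infer_losses, match_peaks, predict_ladder
from nrpsmine.marfey import StandardsTable, assign_peaks
from nrpsmine.residues import Peptide, residue_library
from nrpsmine.simulate import (
    SyntheticClusterSpec,
    biirfg_shaped_spec,
    make_cluster,
    make_marfey,
    make_ms2,
    make_reference,
    random_cluster_spec,
)
from nrpsmine.specificity import extract_code


def test_reference_is_deterministic_per_seed():
    a, b = make_reference(1), make_reference(1)
    assert a.sequence == b.sequence
    assert a.pocket_positions == b.pocket_positions
    assert make_reference(2).sequence != a.sequence


def test_reference_pocket_positions_are_valid():
    for seed in range(5):
        anchor = make_reference(seed)
        pos = anchor.pocket_positions
        assert list(pos) == sorted(set(pos))
        assert len(pos) == 8
        assert pos[0] >= 1 and pos[-1] <= len(anchor.sequence)


def test_reference_carries_the_core_motifs_in_order():
    from nrpsmine.cluster import scan_motifs

    anchor = make_reference(3)
    hits = scan_motifs(anchor.sequence)
    order = []
    for name in ("mA1", "mA3", "mA5", "mA7", "mA10"):
        matches = [h.position for h in hits if h.name == name]
        assert matches, name
        order.append(min(matches))
    assert order == sorted(order)


def test_self_extraction_recovers_planted_pocket_letters():
    anchor = make_reference(4)
    assert extract_code(anchor.sequence, anchor).code == anchor.pocket_letters()


def test_cluster_generation_is_byte_identical_per_seed():
    anchor = make_reference(0)
    spec = biirfg_shaped_spec(seed=9)
    p1, _ = make_cluster(spec, anchor)
    p2, _ = make_cluster(biirfg_shaped_spec(seed=9), anchor)
    assert p1 == p2


def test_biirfg_shaped_cluster_parses_to_complete_architecture():
    anchor = make_reference(0)
    protein, truth = make_cluster(biirfg_shaped_spec(seed=1), anchor)
    arch = truth.architecture
    assert arch.n_modules == 10
    assert arch.n_domains == 28
    assert arch.incomplete_modules() == []
    assert truth.product.peptide.topology == "macrolactone"


def test_single_epimerized_serine_gives_two_to_one_ratio():
    spec = SyntheticClusterSpec(
        modules=[("Ser", False), ("Ser", False), ("Ser", True), ("Gly", False)],
        codes=["AAAAAAAA", "AAAAAAAA", "AAAAAAAA", "CCCCCCCC"],
        seed=2,
    )
    _, truth = make_cluster(spec, make_reference(0))
    sers = [r for r in truth.product.peptide.residues if r.name == "Ser"]
    assert sorted(r.chirality for r in sers) == ["D", "L", "L"]
    rows = make_marfey(truth.product, seed=2)
    by_rt = dict(rows)
    standards = StandardsTable.packaged()
    assert by_rt[standards.rt("L-Ser")] / by_rt[standards.rt("D-Ser")] == pytest.approx(2.0)


def test_zero_jitter_ms2_equals_the_predicted_ladder():
    _, truth = make_cluster(biirfg_shaped_spec(seed=3), make_reference(0))
    peaks = make_ms2(truth.product, ppm_jitter=0.0, n_decoys=0, seed=3)
    linear = Peptide(truth.product.peptide.residues, "linear")
    expected = sorted(f.mz for f in predict_ladder(linear))
    assert peaks.mzs() == pytest.approx(expected, abs=1e-9)


def test_jittered_ms2_is_fully_recalled_at_default_tolerance():
    _, truth = make_cluster(biirfg_shaped_spec(seed=4), make_reference(0))
    peaks = make_ms2(truth.product, ppm_jitter=3.0, n_decoys=0, seed=4)
    linear = Peptide(truth.product.peptide.residues, "linear")
    ladder = predict_ladder(linear)
    match = match_peaks(peaks, ladder, tol_ppm=5.0)
    assert len(match.assignments) == len(ladder)


def test_losses_recovered_through_decoys():
    _, truth = make_cluster(biirfg_shaped_spec(seed=5), make_reference(0))
    peaks = make_ms2(truth.product, ppm_jitter=3.0, n_decoys=50, seed=5)
    losses = infer_losses(peaks, residue_library(), skip_unmatched=True)
    expected = [r.name for r in reversed(truth.product.peptide.residues) if r.kind != "lipid"]
    assert losses[: len(expected)] == expected


def test_zero_jitter_marfey_rows_sit_on_the_standards():
    _, truth = make_cluster(biirfg_shaped_spec(seed=6), make_reference(0))
    rows = make_marfey(truth.product, rt_jitter=0.0, seed=6)
    standards = StandardsTable.packaged()
    standard_rts = {rt for _, rt in standards.entries}
    assert all(rt in standard_rts for rt, _ in rows)
    assignments = assign_peaks(rows, standards)
    assert all(a.matched for a in assignments)


def test_marfey_generation_is_deterministic():
    _, truth = make_cluster(biirfg_shaped_spec(seed=7), make_reference(0))
    assert make_marfey(truth.product, rt_jitter=0.02, seed=7) == make_marfey(
        truth.product, rt_jitter=0.02, seed=7
    )


def test_random_cluster_specs_are_valid_and_deterministic():
    s1 = random_cluster_spec(11)
    s2 = random_cluster_spec(11)
    assert s1.modules == s2.modules and s1.codes == s2.codes
    assert len(s1.codes) == len(s1.modules)


def test_spec_validation_rejects_mismatched_codes():
    with pytest.raises(ValueError):
        SyntheticClusterSpec(modules=[("Ala", False)], codes=[])
    with pytest.raises(ValueError):
        SyntheticClusterSpec(modules=[("Ala", False)], codes=["BAD"])
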