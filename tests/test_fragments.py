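import numpy as np
import pytest

from nrpsmine.chem import PROTON, IonSpec, ion_mz
from nrpsmine.fragments import (
    PROTON_MZ,
    AmbiguityError,
    Peak,
    PeakList,
    infer_losses,
    match_peaks,
    predict_ladder,
)
from nrpsmine.residues import TopologyError, build_peptide, library_residue, residue_library
from nrpsmine.simulate import MASS_DISTINCT_POOL
from .conftest import CALCD, PRINTED_B_SERIES


def _ladder_by_label(peptide):
    return {f.label: f for f in predict_ladder(peptide)}


def test_ladder_reproduces_all_printed_fragment_values(rafflesfungin_linear):
    ladder = _ladder_by_label(rafflesfungin_linear)
    for label in ("b8", "b7", "b6", "b5", "b4", "b3", "b2", "y7", "y6", "y5"):
        assert ladder[label].mz == pytest.approx(CALCD[label], abs=5e-4), label


def test_ladder_fragment_formulas_match_printed_compositions(rafflesfungin_linear):
    ladder = _ladder_by_label(rafflesfungin_linear)
    assert ladder["b8"].formula.to_hill() == "C42H73N8O16"
    assert ladder["y7"].formula.to_hill() == "C24H41N8O15"
    assert ladder["b2"].formula.to_hill() == "C20H38NO3"


def test_ladder_requires_linear_topology(rafflesfungin_cyclic):
    with pytest.raises(TopologyError):
        predict_ladder(rafflesfungin_cyclic)


def test_by_complementarity_on_random_peptides():
    # mz(b_i) + mz(y_{n-i}) = mz([M+H]+) + mz(H+) for every split point
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(3, 10))
        codes = [str(rng.choice(MASS_DISTINCT_POOL)) for _ in range(n)]
        pep = build_peptide(codes, "linear")
        parent = ion_mz(IonSpec(pep.formula + PROTON, 1))
        ladder = _ladder_by_label(pep)
        for i in range(1, n):
            total = ladder[f"b{i}"].mz + ladder[f"y{n - i}"].mz
            assert total == pytest.approx(parent + PROTON_MZ, abs=1e-4)


def test_match_peaks_assigns_printed_observed_values(rafflesfungin_linear):
    obs = PeakList([Peak(m) for m in (945.5151, 844.4669, 757.4343)])
    match = match_peaks(obs, predict_ladder(rafflesfungin_linear), tol_ppm=5.0)
    assert len(match.assignments) == 3
    assert all(frag.series == "b" for _, frag, _ in match.assignments)
    assert [frag.index for _, frag, _ in match.assignments] == [6, 7, 8]


def test_match_peaks_leaves_distant_peaks_unassigned(rafflesfungin_linear):
    obs = PeakList([Peak(500.0)])
    match = match_peaks(obs, predict_ladder(rafflesfungin_linear), tol_ppm=5.0)
    assert match.assignments == []
    assert len(match.unassigned) == 1


def test_match_peaks_full_recall_under_half_tolerance_jitter(rafflesfungin_linear):
    rng = np.random.default_rng(3)
    ladder = predict_ladder(rafflesfungin_linear)
    obs = PeakList([Peak(f.mz * (1 + rng.uniform(-2.5, 2.5) * 1e-6)) for f in ladder])
    match = match_peaks(obs, ladder, tol_ppm=5.0)
    assert len(match.assignments) == len(ladder)
    assert all(abs(err) <= 5.0 for _, _, err in match.assignments)


def test_match_peaks_rejects_empty_prediction():
    with pytest.raises(ValueError):
        match_peaks(PeakList([Peak(100.0)]), [], 5.0)


def test_infer_losses_recovers_the_printed_loss_order(library):
    obs = PeakList([Peak(m) for m in PRINTED_B_SERIES])
    losses = infer_losses(obs, library, parent_mz=CALCD["linear_MH"])
    assert losses == ["Gly", "Thr", "Ser", "Ser", "Ser", "Asn", "Glu"]


def test_single_ladder_step_is_a_serine_loss(library):
    # the printed step 844.4662 -> 757.4342 is one serine residue
    assert 844.4662 - 757.4342 == pytest.approx(library["Ser"].mass, abs=0.01)
    # and through the walker: parent one glycine+water above the top peak
    parent = 844.4662 + library["Gly"].mass + 18.0106
    obs = PeakList([Peak(844.4662), Peak(757.4342)])
    assert infer_losses(obs, library, parent_mz=parent) == ["Gly", "Ser"]


def test_infer_losses_without_threonine_reports_the_unmatched_step():
    lib = {k: library_residue(k) for k in ("Gly", "Ser", "Asn", "Glu", "Ala", "HMHDA")}
    obs = PeakList([Peak(m) for m in PRINTED_B_SERIES])
    with pytest.raises(AmbiguityError, match="101.04"):
        infer_losses(obs, lib, parent_mz=CALCD["linear_MH"])


def test_infer_losses_requires_parent_mass(library):
    with pytest.raises(ValueError):
        infer_losses(PeakList([Peak(500.0)]), library)


def test_noiseless_self_ladder_recovers_residue_order():
    # ladder sequencing inverts ladder prediction for random peptides
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(3, 9))
        codes = [str(rng.choice(MASS_DISTINCT_POOL)) for _ in range(n)]
        pep = build_peptide(codes, "linear")
        parent = ion_mz(IonSpec(pep.formula + PROTON, 1))
        b_peaks = [Peak(f.mz) for f in predict_ladder(pep) if f.series == "b"]
        losses = infer_losses(PeakList(b_peaks), residue_library(), parent_mz=parent)
        # the walk descends b_{n-1}..b_1, losing every residue but the first
        assert losses == list(reversed(codes))[:-1]
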