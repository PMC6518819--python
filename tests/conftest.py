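import pytest

from nrpsmine import build_peptide, hydrolyze
from nrpsmine.cluster import DomainHit
from nrpsmine.residues import residue_library

#: residue order of the study compound: lipid then eight amino acids
RAFFLESFUNGIN_RESIDUES = [
    "HMHDA", "Ala", "Glu", "Asn", "Ser", "Ser", "Ser", "allo-Thr", "Gly",
]

#: printed high-resolution calcd values (Th) for the singly protonated species
CALCD = {
    "cyclic_MH": 1002.5354,
    "linear_MH": 1020.5459,
    "b8": 945.5139,
    "b7": 844.4662,
    "b6": 757.4342,
    "b5": 670.4022,
    "b4": 583.3701,
    "b3": 469.3272,
    "b2": 340.2846,
    "y7": 681.2686,
    "y6": 552.2260,
    "y5": 438.1831,
}

#: observed b-series m/z values as printed, smallest set used for sequencing
PRINTED_B_SERIES = (945.5139, 844.4662, 757.4342, 670.4022, 583.3701, 469.3272, 340.2846)


@pytest.fixture
def rafflesfungin_cyclic():
    return build_peptide(RAFFLESFUNGIN_RESIDUES, "macrolactone")


@pytest.fixture
def rafflesfungin_linear(rafflesfungin_cyclic):
    return hydrolyze(rafflesfungin_cyclic)


@pytest.fixture
def library():
    return residue_library()


def _hits(types):
    """Domain hits with synthetic contiguous coordinates."""
    hits = []
    pos = 0
    for t in types:
        start = pos + 1
        pos += 100
        hits.append(DomainHit(t, start, pos))
    return hits


#: the published NRPS domain listing: initiation PCP, five C-A-PCP modules,
#: two C-A-PCP-E modules, an A-PCP module missing its C, terminal CT
NRPS_DOMAIN_LISTING = (
    ["PCP"]
    + ["C", "A", "PCP"] * 5
    + ["C", "A", "PCP", "E"] * 2
    + ["A", "PCP"]
    + ["CT"]
)

#: the same listing with the recovered condensation domain inserted
NRPS_DOMAIN_LISTING_COMPLETE = (
    ["PCP"]
    + ["C", "A", "PCP"] * 5
    + ["C", "A", "PCP", "E"] * 2
    + ["C", "A", "PCP"]
    + ["CT"]
)


@pytest.fixture
def nrps_hits():
    return _hits(NRPS_DOMAIN_LISTING)


@pytest.fixture
def nrps_hits_complete():
    return _hits(NRPS_DOMAIN_LISTING_COMPLETE)
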