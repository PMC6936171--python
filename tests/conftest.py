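import numpy as np
import pytest

from dielsplice.clock_genes import clock_gene_fixture
from dielsplice.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def clock_fixture():
    """The packaged clock-gene models and their AS event catalogue."""
    return clock_gene_fixture()


@pytest.fixture(scope="session")
def clock_genes(clock_fixture):
    return clock_fixture[0]


@pytest.fixture(scope="session")
def clock_events(clock_fixture):
    return clock_fixture[1]


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic field study (seed 11) shared across tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_two_exon_gene():
    """Minimal plus-strand gene: ATGGCC | GT..AG intron | TAA + short UTR."""
    from dielsplice.gene_models import GeneModel

    exon1 = "ATGGCC"
    intron = "GTATAACCTCTTTTAG"  # GT..AG; TAA in frame once retained
    exon2 = "TAAACGT"
    seq = exon1 + intron + exon2
    return GeneModel(
        gene_id="toy",
        genomic_seq=seq,
        strand="+",
        exons=[(1, len(exon1)), (len(exon1) + len(intron) + 1, len(seq))],
        cds_start=1,
        cds_end=len(exon1) + len(intron) + 3,  # stop = TAA at exon2 start
    )
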