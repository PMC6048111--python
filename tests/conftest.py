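import dataclasses

import numpy as np
import pytest

from fusionsieve.model import FusionCall, GenomicBreakpoint
from fusionsieve.simulate import SimConfig, noiseless


# printed breakpoint pairs of well-characterised colorectal fusions, with
# their published junction separations
TABLE1_BREAKPOINTS = {
    ("STRN", "ALK"): (("chr2", 29446394), ("chr2", 37143221), 7_696_827),
    ("GTF3A", "CDK8"): (("chr13", 26923209), ("chr13", 27999075), 1_075_866),
    ("RNF121", "FOLR2"): (("chr11", 71640170), ("chr11", 71931914), 291_744),
    ("APC", "COMMD10"): (("chr5", 112151290), ("chr5", 115627214), 3_475_924),
    ("ANAPC1", "ZC3H8"): (("chr2", 112614191), ("chr2", 112989507), 375_316),
}


@pytest.fixture
def table1_breakpoints():
    return TABLE1_BREAKPOINTS


def make_call(
    sample="S001",
    caller="caller1",
    donor="GENEA",
    acceptor="GENEB",
    chrom1="chr1",
    pos1=1_000_000,
    chrom2="chr2",
    pos2=2_000_000,
    strand1="+",
    strand2="+",
    spanning=50,
    frame=(0, 0),
) -> FusionCall:
    return FusionCall(
        sample_id=sample,
        caller_id=caller,
        donor_gene=donor,
        acceptor_gene=acceptor,
        bp_donor=GenomicBreakpoint(chrom1, pos1, strand1),
        bp_acceptor=GenomicBreakpoint(chrom2, pos2, strand2),
        spanning_reads=spanning,
        frame_shift=frame,
    )


@pytest.fixture
def call_factory():
    return make_call


SMALL_SIM = SimConfig(
    seed=0, n_patients=30, n_normals=10, n_genes=36, n_true_fusions=8
)


@pytest.fixture
def small_config():
    return SMALL_SIM


@pytest.fixture
def small_noiseless_config():
    return noiseless(SMALL_SIM)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
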