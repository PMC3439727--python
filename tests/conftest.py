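import numpy as np
import pytest

import matefill as mf


@pytest.fixture(scope="session")
def mini_world():
    """A small error-free simulated experiment shared by slower tests.

    6 kb random genome, 40x forward-reverse pairs (100 bp reads, insert
    400 +/- 30), with truth coordinates.
    """
    genome = mf.make_genome(6000, seed=11)
    lib = mf.make_pairs(genome, 40, 100, 400, 30, err_rate=0.0, seed=12)
    pairs = [(f"p{i}", lib.reads1[i], lib.reads2[i]) for i in range(len(lib))]
    return genome, lib, pairs


@pytest.fixture(scope="session")
def mini_index(mini_world):
    _, _, pairs = mini_world
    reads = []
    rid = 0
    for _, s1, s2 in pairs:
        reads.append(mf.Read(rid, mf.encode_seq(s1), mate_id=rid + 1, pair_order=1))
        reads.append(mf.Read(rid + 1, mf.encode_seq(s2), mate_id=rid, pair_order=2))
        rid += 2
    return mf.build_index(reads, mf.FingerprintParams(), L=50)


@pytest.fixture
def mini_params():
    return mf.ExtensionParams(avg_read_len=100, Lmax=490)
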