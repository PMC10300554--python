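import numpy as np
import pytest

from asomics.capturec import BaitSet, ReferenceIndex
from asomics.simulate import SimConfig, make_reference


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=42, genome_length=100_000, n_read_pairs=1_000)


@pytest.fixture(scope="session")
def small_ref(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def small_baits(small_ref):
    frags = small_ref.chrom_fragments("chr1")
    mid = frags[len(frags) // 2]
    return BaitSet.from_fragments(small_ref, [mid.fragment_id], ids=["b1"])


@pytest.fixture
def tiny_ref():
    """Hand-built two-chromosome reference with known GATC layout."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACT", dtype=np.uint8)  # G-free: no accidental GATC

    def random_seq(n):
        return bases[rng.integers(0, 3, n)].tobytes().decode()

    # fragments of controlled lengths joined by explicit GATC sites
    seq1 = random_seq(60) + "GATC" + random_seq(46) + "GATC" + random_seq(96)
    seq2 = random_seq(80) + "GATC" + random_seq(120)
    return ReferenceIndex({"chr1": seq1, "chr2": seq2})
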