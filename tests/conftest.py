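import numpy as np
import pytest

from rdcnv import ChromSizes, GenomicInterval, build_genome
from rdcnv.simulate import SimGenomeConfig


@pytest.fixture(scope="session")
def genome():
    """Default reduced-scale synthetic genome shared across tests."""
    return build_genome(seed=11)


@pytest.fixture(scope="session")
def small_sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


def random_intervals(rng, chroms, n, max_len=5_000):
    out = []
    for _ in range(n):
        chrom, length = chroms[rng.integers(0, len(chroms))]
        size = int(rng.integers(1, max_len))
        start = int(rng.integers(0, length - size))
        out.append(GenomicInterval(chrom, start, start + size))
    return out
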