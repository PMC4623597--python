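import numpy as np
import pandas as pd
import pytest

from epicon.chains import Chain, ChainBlock
from epicon.sim import SimulationConfig, simulate_genome_pair


@pytest.fixture
def simple_chain():
    """chr1:100-200 aligned contiguously to chrA:1000-1100."""
    return Chain(
        100.0, "chr1", 10_000, 100, 200, "chrA", 20_000, "+", 1000, 1100,
        [ChainBlock(100)],
    )


@pytest.fixture
def minus_chain():
    """chr1:0-100 aligned to chrB minus-strand positions 100-200 (size 1000)."""
    return Chain(
        100.0, "chr1", 10_000, 0, 100, "chrB", 1000, "-", 100, 200,
        [ChainBlock(100)],
    )


@pytest.fixture
def gapped_chain():
    """Two 100 bp blocks separated by a 100 bp source (dt) gap."""
    return Chain(
        100.0, "chr1", 10_000, 0, 300, "chrC", 1000, "+", 0, 200,
        [ChainBlock(100, 100, 0), ChainBlock(100)],
    )


@pytest.fixture
def random_genome_pair():
    cfg = SimulationConfig(
        seed=7,
        chrom_sizes={"chrA1": 60_000, "chrA2": 40_000},
        insertion_rate=1e-4, deletion_rate=1e-4,
        inversion_rate=3e-5, break_rate=1e-5, event_size_mean=300,
    )
    return simulate_genome_pair(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
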