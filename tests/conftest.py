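import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from pseudomap.epcr import PrimerIndex
from pseudomap.synthetic import make_genome, plant_primer_pairs


@pytest.fixture(scope="session")
def small_genome():
    """Two 30 kb random chromosomes (seed 11)."""
    genome, log = make_genome(11, n_chrom=2, lengths=[30_000, 30_000])
    return genome, log


@pytest.fixture(scope="session")
def small_index(small_genome):
    genome, _ = small_genome
    return PrimerIndex(genome, word_size=12)


@pytest.fixture(scope="session")
def planted_epcr():
    """A 100 kb genome with 20 planted primer pairs (seed 1)."""
    genome, log = make_genome(1, n_chrom=2, lengths=[50_000, 50_000])
    pairs = plant_primer_pairs(genome, log, n=20, seed=1)
    return genome, log, pairs
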