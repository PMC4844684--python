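import numpy as np
import pytest

from ntskew import _seq
from ntskew.genome_io import AnnotatedGenome, OrientedInterval
from ntskew.pipeline import genome_skews
from ntskew.simulate import SyntheticTruth, generate_synthetic_genome


@pytest.fixture(scope="session")
def toy_annotation():
    """The worked 10-kb circle: three operons, one wrapped trimmed gap."""
    L = 10_000
    rng = np.random.default_rng(0)
    seq = rng.integers(0, 4, size=L).astype(np.int8)
    feats = [
        OrientedInterval(100, 2000, "+", "operon", "op1"),
        OrientedInterval(2300, 4000, "-", "operon", "op2"),
        OrientedInterval(6000, 9500, "+", "operon", "op3"),
    ]
    return AnnotatedGenome("toy", seq, 0, feats)


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-size synthetic genome parameters for fast unit tests."""
    return SyntheticTruth(n_operons=16, units_per_gene=60, gap_len=600, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_truth):
    genome, truth = generate_synthetic_genome(small_truth, genome_id="small")
    return genome, truth


@pytest.fixture(scope="session")
def small_skews(small_genome):
    genome, _ = small_genome
    return genome_skews(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
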