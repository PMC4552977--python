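import numpy as np
import pytest

from rrgsim.genome import GeneticMap, MeiosisParams
from rrgsim.io import make_toy_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    """Miniature deterministic study (burn-in + calibrated founders)."""
    return make_toy_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def small_fixture():
    return make_toy_fixture("small", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_map():
    """2 chromosomes x 0.5 Morgan, 40 equally spaced loci."""
    return GeneticMap.uniform(n_chromosomes=2, total_length=1.0, n_loci=40)


@pytest.fixture
def no_mutation():
    return MeiosisParams(mutation_rate=0.0)
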