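import numpy as np
import pytest

from rareprob import GenotypeMatrix, Phenotypes, SimConfig, sim_fixed


@pytest.fixture
def rng():
    return np.random.default_rng(20130121)


@pytest.fixture
def small_dataset():
    """A small strong-signal dataset: 20 variants, 200 genotypes."""
    return sim_fixed(SimConfig(m=20, k=5, n=200, delta=0.3, seed=7))


@pytest.fixture
def tiny_genotypes():
    values = np.array([[0, 1, 0, 1], [1, 0, 0, 0], [1, 1, 1, 0]], dtype=np.int8)
    return GenotypeMatrix(values, ["v1", "v2", "v3"], ["a", "b", "c", "d"])


@pytest.fixture
def tiny_phenotypes():
    return Phenotypes(np.array([1, 1, 0, 0]))
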