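import numpy as np
import pytest

from lincphylo.config import PipelineConfig, ScoringScheme
from lincphylo.simulate import SimParams, default_species_tree, simulate


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(rng_seed=11)


@pytest.fixture(scope="session")
def fixture_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def small_sim():
    """A 30-locus simulation shared by homology/families/loss-decay tests."""
    return simulate(SimParams(n_loci=30, rng_seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
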