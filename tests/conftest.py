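import numpy as np
import pytest
from hypothesis import settings

from ltsp import PassageScheme, SimulationParams, synthetic_trajectory_table

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scaled_params():
    """Full census sizes, but only a 4.6 kb genomic region is simulated.

    Keeps the drift/bottleneck dynamics exact while making the per-passage
    mutation supply (~29 expected new lineages) trackable.
    """
    return SimulationParams(genome_length=4_600)


@pytest.fixture
def neutral_params():
    return SimulationParams(genome_length=4_600, mutation_rate=0.0)


@pytest.fixture
def scheme():
    return PassageScheme()


@pytest.fixture(scope="session")
def fixture_table():
    """213-unique-allele trajectory table with the reference composition."""
    return synthetic_trajectory_table(seed=7)
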