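import numpy as np
import pytest

from gvannot.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic genome (seed 1) with its truth table."""
    return simulate_genome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A compact genome for cheaper end-to-end tests."""
    return simulate_genome(SimulationConfig(seed=3, genome_len=30_000, n_orfs=30))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
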