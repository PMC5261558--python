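import numpy as np
import pytest

from cd5switch.simulate import SimulationConfig, assign_cd5_states, simulate_clone

BASES = "ACGT"


def random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    return ["".join(BASES[i] for i in rng.integers(0, 4, size=length)) for _ in range(n)]


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast simulation config used across tests."""
    return SimulationConfig(seed=7, clone_cells=300, background_clones=20, reads_per_cell=4)


@pytest.fixture(scope="session")
def truth_c(small_config):
    """A scenario-C truth with states assigned (session-cached, read-only)."""
    truth = simulate_clone(small_config)
    return assign_cd5_states(truth, "C", 0.15, seed=7)


def gate_sets(truth):
    high = {c.bcr_sequence for c in truth.cells if c.cd5_state == "high"}
    low = {c.bcr_sequence for c in truth.cells if c.cd5_state == "low"}
    return high, low
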