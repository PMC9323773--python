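import numpy as np
import pytest

from hervtrace.simulate import (SimulationConfig, emit_reference_panels,
                                simulate_cohort, simulate_discovery_genome)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight orthologous insertions over the 6-leaf fixture tree.

    Insertion 4 is lost in Pan, leaving a Homo+Gorilla-only orthology
    group dated at the 9.1 MYA split.
    """
    cfg = SimulationConfig(
        seed=5, n_insertions=8,
        insertion_nodes=("node0", "node1", "node2", "node3", "node1",
                         "node2", "node0", "node1"),
        losses={4: ("Pan_troglodytes",)})
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_genome():
    """Twelve planted full-length elements plus an element-free control."""
    genome, control, truth, cfg = simulate_discovery_genome(n_elements=12,
                                                            seed=1)
    return genome, control, truth, cfg


@pytest.fixture(scope="session")
def panels(small_genome):
    return emit_reference_panels(small_genome[3])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
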