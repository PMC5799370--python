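import numpy as np
import pytest

import netmed as nm


@pytest.fixture
def path_graph():
    """A -- B -- C -- D."""
    return nm.Interactome.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def two_components():
    """A--B and C--D, disconnected."""
    return nm.Interactome.from_edges([("A", "B"), ("C", "D")])


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic scenario shared by read-only tests."""
    return nm.generate_scenario(nm.ScenarioConfig(master_seed=42))


def random_interactome(n: int, p: float, seed: int) -> nm.Interactome:
    """Small uniform random graph for oracle comparisons."""
    cfg = nm.ScenarioConfig(n_nodes=max(n, 5), mode="erdos_renyi",
                            edge_probability=p, master_seed=seed)
    return nm.generate_interactome(cfg)
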