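import numpy as np
import pytest

import nsiasd as ns


@pytest.fixture
def two_node_net():
    """Single edge a-b: W = [[0,1],[1,0]]."""
    return ns.network_from_edges([("a", "b", 900)])


@pytest.fixture
def star_net():
    """Star with center 'c' and four leaves."""
    edges = [("c", leaf, 800) for leaf in ["l1", "l2", "l3", "l4"]]
    return ns.network_from_edges(edges)


@pytest.fixture
def path3_net():
    """Path a-b-c."""
    return ns.network_from_edges([("a", "b", 900), ("b", "c", 900)])


@pytest.fixture(scope="session")
def small_scenario():
    """300-node planted-module benchmark shared across tests."""
    sc = ns.SyntheticScenario(n_nodes=300, module_size=30,
                              module_edge_density=0.25, n_lists=3,
                              list_coverage=0.4, n_pathways=20,
                              pathway_size_range=(10, 40), rng_seed=1)
    return ns.generate_scenario(sc)


def random_network(n, p, seed, prefix="g"):
    """Erdos-Renyi helper used by solver-equivalence and null tests."""
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((f"{prefix}{i:04d}", f"{prefix}{j:04d}", 900))
    if not edges:
        edges = [(f"{prefix}0000", f"{prefix}0001", 900)]
    return ns.network_from_edges(edges)
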