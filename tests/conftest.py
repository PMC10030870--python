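import numpy as np
import pytest

import neulay as nl


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def path_graph():
    """0-1-2 path from edge-list text."""
    return nl.read_graph("0 1\n1 2", "edgelist")


@pytest.fixture(scope="session")
def small_er():
    return nl.er_graph(12, 0.35, seed=7)


@pytest.fixture(scope="session")
def sbm4():
    """The 4-block benchmark: 100 nodes, blocks of 25, p_in=0.5, p_out=0.02."""
    graph, partition = nl.sbm_graph([25] * 4, 0.5, 0.02, seed=3, return_partition=True)
    return graph, partition


def random_weighted_graph(n, p, seed):
    """ER topology with random positive weights (for exactness oracles)."""
    rng = np.random.default_rng(seed)
    g = nl.er_graph(n, p, seed=seed).to_networkx()
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
    return nl.Graph.from_networkx(g)
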