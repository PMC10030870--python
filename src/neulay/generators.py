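"""Seeded synthetic graph generators: the benchmark families.

Erdős–Rényi and Barabási–Albert graphs lack large-scale geometric or
community structure; stochastic block models (communities) and random
geometric graphs (spatial proximity) carry outlier eigenvalues in their
adjacency spectrum, which is exactly the regime where the neural
reparametrization accelerates layout.  The cubic lattice is the small fixture
with a known optimal layout.

All generators are deterministic under a fixed integer seed and return
:class:`~neulay.graph.Graph` objects (symmetric, zero diagonal, unweighted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import CommunityPartition, Graph

__all__ = [
    "GeneratorSpec",
    "er_graph",
    "ba_graph",
    "sbm_graph",
    "rgg_graph",
    "cubic_lattice",
    "generate",
]


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


def er_graph(n: int, p: float, seed: int | None = None) -> Graph:
    """Erdős–Rényi G(n, p): each unordered pair linked independently w.p. p."""
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_prob(p, "p")
    return Graph.from_networkx(nx.fast_gnp_random_graph(n, p, seed=seed))


def ba_graph(n: int, m: int, seed: int | None = None) -> Graph:
    """Barabási–Albert preferential attachment from a complete m-node seed.

    Each new node attaches m links to existing nodes with probability
    proportional to degree, so the link count is m(n-m) plus the m(m-1)/2
    links of the seed clique.
    """
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=nx.complete_graph(m))
    return Graph.from_networkx(g)


def sbm_graph(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int | None = None,
    return_partition: bool = False,
):
    """Stochastic block model: within-block pairs linked w.p. p_in, cross w.p. p_out.

    The planted partition (block index per node) is returned alongside the
    graph when ``return_partition`` is true; downstream localization metrics
    consume it.  The speedup analysis assumes assortative structure, so
    p_in <= p_out only triggers a warning, not an error.
    """
    _check_prob(p_in, "p_in")
    _check_prob(p_out, "p_out")
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    if p_in <= p_out:
        warnings.warn(
            "p_in <= p_out: graph is not assortative; the outlier-eigenvalue "
            "speedup analysis does not apply",
            stacklevel=2,
        )
    g = nx.stochastic_block_model(list(block_sizes), _sbm_matrix(block_sizes, p_in, p_out), seed=seed)
    graph = Graph.from_networkx(nx.Graph(g))
    if not return_partition:
        return graph
    labels = {}
    node = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            labels[node] = b
            node += 1
    return graph, CommunityPartition(labels)


def _sbm_matrix(block_sizes, p_in, p_out):
    k = len(block_sizes)
    return [[p_in if i == j else p_out for j in range(k)] for i in range(k)]


def rgg_graph(
    n: int,
    radius: float,
    spatial_dim: int = 2,
    seed: int | None = None,
    return_positions: bool = False,
):
    """Random geometric graph: n uniform points in the unit hypercube, linked
    iff their Euclidean distance is <= radius (hard walls, no wrap-around).

    The planted positions are returned on request for tests; the layout
    algorithms never see them.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if spatial_dim not in (2, 3):
        raise ValueError("spatial_dim must be 2 or 3")
    g = nx.random_geometric_graph(n, radius, dim=spatial_dim, seed=seed)
    graph = Graph.from_networkx(g)
    if not return_positions:
        return graph
    pos = nx.get_node_attributes(g, "pos")
    order = np.array([pos[v] for v in sorted(pos)], dtype=float)
    return graph, order


def cubic_lattice(side: int) -> Graph:
    """Simple cubic lattice: side^3 nodes on integer grid points, links between
    unit-distance neighbors; 3 * side^2 * (side - 1) links."""
    if side < 1:
        raise ValueError("side must be >= 1")
    g = nx.grid_graph(dim=[side, side, side])
    g = nx.relabel_nodes(g, {v: f"{v[0]:02d}_{v[1]:02d}_{v[2]:02d}" for v in g})
    return Graph.from_networkx(g)


@dataclass
class GeneratorSpec:
    """Declarative generator configuration used by the benchmark harness."""

    family: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def build(self):
        """Instantiate the graph (plus partition for SBM)."""
        fam = self.family.lower()
        p = dict(self.parameters)
        if fam == "er":
            return er_graph(p["n"], p["p"], seed=self.seed)
        if fam == "ba":
            return ba_graph(p["n"], p["m"], seed=self.seed)
        if fam == "sbm":
            return sbm_graph(
                p["block_sizes"], p["p_in"], p["p_out"], seed=self.seed,
                return_partition=p.get("return_partition", False),
            )
        if fam == "rgg":
            return rgg_graph(
                p["n"], p["radius"], p.get("spatial_dim", 2), seed=self.seed
            )
        if fam == "lattice":
            return cubic_lattice(p["side"])
        raise ValueError(f"unknown generator family {self.family!r}")


def generate(family: str, seed: int | None = None, **parameters):
    """Convenience wrapper: ``generate("sbm", block_sizes=[25]*4, p_in=0.5, ...)``."""
    return GeneratorSpec(family, parameters, seed).build()
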