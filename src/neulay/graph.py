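"""Graph and layout containers plus readers/writers for standard formats.

The graph model is deliberately small: an ordered list of node labels and a
symmetric, zero-diagonal, non-negative sparse adjacency matrix.  All matrices
produced elsewhere in the package (Laplacian, normalized GCN operator,
spectral splits) are indexed by the node order stored here, which is the
sorted order of the labels so that repeated reads of the same file give
byte-identical downstream results.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Graph",
    "Layout",
    "CommunityPartition",
    "GraphFormatError",
    "read_graph",
    "write_graph",
    "read_partition",
    "write_layout",
    "read_layout",
    "laplacian",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


def _sort_key(label):
    # Numeric labels sort numerically, everything else lexically; mixed sets
    # fall back to the string form so sorting never raises.
    try:
        return (0, float(label), str(label))
    except (TypeError, ValueError):
        return (1, 0.0, str(label))


@dataclass(frozen=True)
class Graph:
    """Undirected weighted graph with a fixed node order.

    Attributes
    ----------
    node_ids:
        Node labels in the canonical (sorted) order.  Row/column ``i`` of
        :attr:`adjacency` corresponds to ``node_ids[i]``.
    adjacency:
        Symmetric non-negative CSR matrix with zero diagonal.
    """

    node_ids: tuple
    adjacency: sp.csr_matrix

    def __post_init__(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.node_ids):
            raise ValueError("adjacency shape does not match node_ids")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_links(self) -> int:
        """Number of unordered linked pairs."""
        return int(sp.triu(self.adjacency, k=1).nnz)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of each node (row sums of the adjacency)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def index_of(self, node_id) -> int:
        try:
            return self._index[node_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {v: i for i, v in enumerate(self.node_ids)}
            )
            return self._index[node_id]

    def edge_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, w) arrays over unordered pairs i < j with nonzero weight."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return coo.row, coo.col, coo.data

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        i, j, w = self.edge_array()
        g.add_weighted_edges_from(
            (self.node_ids[a], self.node_ids[b], float(c)) for a, b, c in zip(i, j, w)
        )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, *, binarize: bool = False) -> "Graph":
        """Build a Graph from a networkx graph.

        Self-loops are dropped (their elastic energy is constant and the GCN
        operator adds the identity itself); parallel edges, if the input is a
        multigraph, collapse to the maximum weight.
        """
        n_self = nx.number_of_selfloops(g)
        if n_self:
            warnings.warn(f"dropped {n_self} self-loop(s)", stacklevel=2)
        nodes = sorted(g.nodes(), key=_sort_key)
        index = {v: i for i, v in enumerate(nodes)}
        best: dict[tuple[int, int], float] = {}
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            w = float(data.get("weight", 1.0))
            if w < 0:
                raise ValueError(f"negative edge weight on ({u}, {v})")
            if binarize:
                w = 1.0
            key = (index[u], index[v]) if index[u] < index[v] else (index[v], index[u])
            if w > best.get(key, -np.inf):
                best[key] = w
        n = len(nodes)
        if best:
            ij = np.array(list(best.keys()), dtype=np.int64)
            w = np.array(list(best.values()))
            keep = w > 0
            ij, w = ij[keep], w[keep]
            adj = sp.coo_matrix(
                (np.r_[w, w], (np.r_[ij[:, 0], ij[:, 1]], np.r_[ij[:, 1], ij[:, 0]])),
                shape=(n, n),
            ).tocsr()
        else:
            adj = sp.csr_matrix((n, n))
        return cls(tuple(nodes), adj)


@dataclass
class Layout:
    """Node coordinates: an N x d real matrix, d in {2, 3}, unitless."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be N x d with d in {2, 3}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class CommunityPartition:
    """Map node_id -> community label; consumed by localization metrics."""

    labels: dict

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def as_array(self, graph: Graph) -> np.ndarray:
        """Labels in the graph's node order; raises if any node is unlabeled."""
        missing = [v for v in graph.node_ids if v not in self.labels]
        if missing:
            raise ValueError(f"{len(missing)} node(s) unlabeled, e.g. {missing[0]!r}")
        return np.asarray([self.labels[v] for v in graph.node_ids], dtype=object)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_edgelist(text: str) -> nx.Graph:
    g = nx.Graph()
    n_self = 0
    seen_any = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise GraphFormatError(
                f"line {lineno}: expected 'u v [weight]', got {raw!r}"
            )
        u, v = parts[0], parts[1]
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError:
                raise GraphFormatError(
                    f"line {lineno}: weight {parts[2]!r} is not a number"
                ) from None
        else:
            w = 1.0
        seen_any = True
        if u == v:
            n_self += 1
            continue
        if not g.has_edge(u, v) or g[u][v]["weight"] < w:
            g.add_edge(u, v, weight=w)
    if not seen_any:
        raise GraphFormatError("empty edge list")
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s)", stacklevel=3)
    return g


def read_graph(source, format: str = "edgelist", *, binarize: bool = False) -> Graph:
    """Read a graph from a path or raw text.

    Parameters
    ----------
    source:
        A file path, or (for ``edgelist``) the raw text itself when it contains
        a newline or parses as an edge list and no such file exists.
    format:
        One of ``edgelist`` ("u v [weight]" per line, ``#`` comments),
        ``gml`` or ``graphml``.
    binarize:
        Replace every positive edge weight by 1 (real-network weights are kept
        by default).
    """
    fmt = format.lower()
    if fmt == "edgelist":
        if isinstance(source, (str, Path)) and Path(str(source)).is_file():
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            raise GraphFormatError(f"no such file: {source}")
        return Graph.from_networkx(_parse_edgelist(text), binarize=binarize)
    if fmt == "gml":
        try:
            g = nx.read_gml(str(source), label="label")
        except Exception as exc:  # networkx raises several parser types
            raise GraphFormatError(f"cannot parse GML {source}: {exc}") from exc
    elif fmt == "graphml":
        try:
            g = nx.read_graphml(str(source))
        except Exception as exc:
            raise GraphFormatError(f"cannot parse GraphML {source}: {exc}") from exc
    else:
        raise ValueError(f"unknown graph format {format!r}")
    if g.number_of_nodes() == 0:
        raise GraphFormatError(f"empty graph in {source}")
    return Graph.from_networkx(nx.Graph(g), binarize=binarize)


def write_graph(graph: Graph, path, format: str = "gml") -> None:
    """Write a graph as GML, GraphML or an edge list."""
    fmt = format.lower()
    g = graph.to_networkx()
    if fmt == "gml":
        nx.write_gml(g, str(path), stringizer=str)
    elif fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "edgelist":
        lines = [
            f"{graph.node_ids[i]} {graph.node_ids[j]} {w:.17g}"
            for i, j, w in zip(*graph.edge_array())
        ]
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_partition(source) -> CommunityPartition:
    """Read a two-column "node_id label" text file (``#`` comments allowed)."""
    text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
    labels = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphFormatError(f"line {lineno}: expected 'node_id label'")
        labels[parts[0]] = parts[1]
    if not labels:
        raise GraphFormatError("empty partition file")
    return CommunityPartition(labels)


def write_layout(graph: Graph, layout: Layout, path=None, format: str = "csv"):
    """Serialize a layout; returns the text (and writes it if ``path`` given).

    CSV columns are ``node_id,x,y[,z]`` in node order; JSON maps node_id to
    its coordinate list.  Full float precision is kept so that a write/read
    round trip is exact.
    """
    if layout.n != graph.n_nodes:
        raise ValueError(
            f"layout has {layout.n} rows but graph has {graph.n_nodes} nodes"
        )
    fmt = format.lower()
    if fmt == "csv":
        header = "node_id," + ",".join("xyz"[: layout.dim])
        rows = [
            str(v) + "," + ",".join(repr(float(c)) for c in row)
            for v, row in zip(graph.node_ids, layout.coords)
        ]
        text = "\n".join([header] + rows) + "\n"
    elif fmt == "json":
        text = json.dumps(
            {str(v): [float(c) for c in row] for v, row in zip(graph.node_ids, layout.coords)},
            indent=1,
        )
    else:
        raise ValueError(f"unknown layout format {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def read_layout(source, graph: Graph | None = None, format: str = "csv") -> Layout:
    """Read a layout written by :func:`write_layout`.

    If ``graph`` is given, rows are reordered to the graph's node order and
    completeness is checked.
    """
    text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
    fmt = format.lower()
    coords: dict[str, list[float]] = {}
    if fmt == "csv":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for ln in lines[1:]:
            parts = ln.split(",")
            coords[parts[0]] = [float(x) for x in parts[1:]]
    elif fmt == "json":
        coords = {k: [float(x) for x in v] for k, v in json.loads(text).items()}
    else:
        raise ValueError(f"unknown layout format {format!r}")
    if graph is None:
        return Layout(np.array(list(coords.values())))
    try:
        rows = [coords[str(v)] for v in graph.node_ids]
    except KeyError as exc:
        raise ValueError(f"layout is missing node {exc.args[0]!r}") from None
    return Layout(np.array(rows))


def laplacian(graph: Graph) -> sp.csr_matrix:
    """Graph Laplacian L = D - A with D_ii = sum_k A_ik (sparse, PSD)."""
    a = graph.adjacency
    d = sp.diags(np.asarray(a.sum(axis=1)).ravel())
    return (d - a).tocsr()
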