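"""Layout-quality and speed measures.

Quality: final energy (and the FDL-to-model energy ratio), link-length
distributions (globally and per community), cluster separation (silhouette),
and a geometric-randomization null that permutes which node sits at which
coordinate while keeping the coordinate multiset and the graph fixed — a
layout is "geometrically informative" when its link lengths are shorter than
under this null.

Speed: steps/seconds to reach within a fraction delta of a target energy
(by default the paired direct-FDL final energy) and the corresponding
speedup ratios.  Step counts are hardware-independent; wall-clock ratios are
reported but depend on the machine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_samples

from .fdl import Trajectory
from .graph import CommunityPartition, Graph, Layout

__all__ = [
    "LengthHistogram",
    "energy_ratio",
    "convergence_time",
    "speedup",
    "link_lengths",
    "link_length_distribution",
    "community_length_distributions",
    "geometric_randomization",
    "cluster_separation",
]

NOT_REACHED = None  # sentinel for trajectories that never hit the target


@dataclass
class LengthHistogram:
    """Histogram of Euclidean link lengths plus summary statistics."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    median: float
    q75: float
    n_links: int


def energy_ratio(e_fdl: float, e_model: float) -> float:
    """Delta-E = E_FDL / E_model; > 1 means the model found a deeper minimum."""
    if e_fdl <= 0 or e_model <= 0:
        raise ValueError("energy ratio requires positive energies")
    return e_fdl / e_model


def convergence_time(
    traj: Trajectory, e_target: float, delta: float = 0.05
) -> tuple[int | None, float | None]:
    """(step, seconds) of the first recorded step with E <= (1 + delta) * e_target,
    or (None, None) if the target is never reached."""
    if not traj.steps:
        raise ValueError("empty trajectory")
    thresh = (1.0 + delta) * e_target
    for s, e, t in zip(traj.steps, traj.energies, traj.wall_times):
        if e <= thresh:
            return s, t
    return NOT_REACHED, NOT_REACHED


def speedup(
    traj_fdl: Trajectory,
    traj_model: Trajectory,
    delta: float = 0.05,
    e_target: float | None = None,
) -> tuple[float | None, float | None]:
    """(step_ratio, time_ratio): FDL cost over model cost to reach the target.

    The default target is the FDL run's own final energy.  ``None`` entries
    propagate when either trajectory never reaches the target.
    """
    if e_target is None:
        e_target = traj_fdl.final_energy
    sf, tf = convergence_time(traj_fdl, e_target, delta)
    sm, tm = convergence_time(traj_model, e_target, delta)
    if sf is NOT_REACHED or sm is NOT_REACHED:
        return NOT_REACHED, NOT_REACHED
    step_ratio = sf / sm if sm > 0 else (1.0 if sf == 0 else np.inf)
    time_ratio = tf / tm if tm > 0 else (1.0 if tf == 0 else np.inf)
    return step_ratio, time_ratio


def link_lengths(graph: Graph, layout: Layout) -> np.ndarray:
    """Euclidean length of every link, in the edge order of the graph."""
    if layout.n != graph.n_nodes:
        raise ValueError("layout does not match graph")
    i, j, _ = graph.edge_array()
    return np.linalg.norm(layout.coords[i] - layout.coords[j], axis=1)


def _histogram(lengths: np.ndarray, bins: int) -> LengthHistogram:
    upper = float(lengths.max()) if len(lengths) else 1.0
    edges = np.linspace(0.0, upper if upper > 0 else 1.0, bins + 1)
    counts, edges = np.histogram(lengths, bins=edges)
    if len(lengths) == 0:
        return LengthHistogram(edges, counts, np.nan, np.nan, np.nan, 0)
    return LengthHistogram(
        edges,
        counts,
        float(lengths.mean()),
        float(np.median(lengths)),
        float(np.quantile(lengths, 0.75)),
        int(len(lengths)),
    )


def link_length_distribution(graph: Graph, layout: Layout, bins: int = 50) -> LengthHistogram:
    """Histogram of all link lengths over [0, max length]."""
    return _histogram(link_lengths(graph, layout), bins)


def community_length_distributions(
    graph: Graph, layout: Layout, partition: CommunityPartition, bins: int = 50
) -> dict:
    """Per-community histograms of *internal* link lengths (cross-community
    links are excluded).  A spatially localized community has a narrow one."""
    labels = partition.as_array(graph)
    i, j, _ = graph.edge_array()
    lengths = np.linalg.norm(layout.coords[i] - layout.coords[j], axis=1)
    out = {}
    for lab in sorted(set(labels.tolist()), key=str):
        mask = (labels[i] == lab) & (labels[j] == lab)
        out[lab] = _histogram(lengths[mask], bins)
    return out


def geometric_randomization(layout: Layout, seed: int | None = None) -> Layout:
    """Permute which node occupies which coordinate, keeping the coordinate
    multiset (and, implicitly, the adjacency) unchanged."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(layout.n)
    return Layout(layout.coords[perm])


def cluster_separation(
    layout: Layout, partition: CommunityPartition, graph: Graph | None = None
) -> float:
    """Mean silhouette coefficient of the nodes in layout space, using the
    community labels as cluster assignments; in [-1, 1], higher means better
    spatially separated communities.

    Singleton communities carry no within-cluster distance; their nodes are
    skipped with a warning.
    """
    if graph is not None:
        labels = partition.as_array(graph)
    else:
        labels = np.asarray(
            [partition.labels[k] for k in sorted(partition.labels, key=str)],
            dtype=object,
        )
    if len(labels) != layout.n:
        raise ValueError("partition does not match layout size")
    labs, counts = np.unique(labels.astype(str), return_counts=True)
    if len(labs) < 2:
        raise ValueError("cluster separation requires at least 2 communities")
    singletons = set(labs[counts == 1])
    if singletons:
        warnings.warn(
            f"skipping {len(singletons)} singleton community(ies)", stacklevel=2
        )
        keep = np.asarray([str(l) not in singletons for l in labels])
        labels, coords = labels[keep], layout.coords[keep]
        if len(np.unique(labels.astype(str))) < 2:
            raise ValueError("fewer than 2 non-singleton communities")
    else:
        coords = layout.coords
    return float(np.mean(silhouette_samples(coords, labels.astype(str))))
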