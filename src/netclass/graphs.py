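"""Thresholded weighted brain graphs and the six nodal graph metrics.

Connectivity matrices become undirected weighted graphs whose nodes are
atlas regions; edges are the suprathreshold weights.  Shortest paths use
the brain-connectivity-toolbox convention of edge length = 1/weight, so a
strong connection is a short path.  Per node the module computes global
efficiency, local efficiency, degree, strength, the Onnela weighted
clustering coefficient, and (unnormalized) betweenness centrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "WeightedGraph",
    "threshold_adjacency",
    "weighted_shortest_paths",
    "nodal_graph_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "global_efficiency",
    "local_efficiency",
    "degree",
    "strength",
    "clustering_coefficient",
    "betweenness_centrality",
)


@dataclass
class WeightedGraph:
    """Undirected weighted graph: symmetric non-negative weights, no self-loops."""

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.nodes) != w.shape[0]:
            raise ValueError("node labels must match matrix size")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def threshold_adjacency(
    matrix: np.ndarray,
    threshold: float,
    positive_only: bool = True,
    nodes: list[str] | None = None,
) -> WeightedGraph:
    """Keep edges with weight strictly above ``threshold`` (and above 0 when
    ``positive_only``); kept edges retain their weights, all others are 0.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError("connectivity matrix must be symmetric")
    keep = mat > threshold
    if positive_only:
        keep &= mat > 0
    w = np.where(keep, mat, 0.0)
    if np.any(w < 0):
        raise ValueError(
            "thresholding kept negative weights; use positive_only=True or a non-negative threshold"
        )
    if nodes is None:
        nodes = [f"roi_{i}" for i in range(mat.shape[0])]
    return WeightedGraph(nodes=list(nodes), weights=w)


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return lengths


def weighted_shortest_paths(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest path distances with edge length 1/weight.

    Disconnected pairs are ``inf``; the diagonal is 0.
    """
    n = graph.n_nodes
    if n == 0:
        return np.zeros((0, 0))
    lengths = csr_matrix(_length_matrix(graph.weights))
    dist = dijkstra(lengths, directed=False)
    return dist


def _efficiency_from_distances(dist: np.ndarray) -> np.ndarray:
    """Per-node mean of inverse distances to all other nodes (1/inf -> 0)."""
    n = dist.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_graph_metrics(graph: WeightedGraph) -> pd.DataFrame:
    """The six nodal weighted-graph metrics, one row per node.

    * global efficiency: mean inverse shortest-path distance to all others;
    * local efficiency: mean global efficiency of the subgraph induced by
      the node's neighbors (original weights);
    * degree: number of incident edges; strength: sum of incident weights;
    * clustering coefficient: Onnela geometric-mean-of-triangle-weights form
      (weights rescaled by the network maximum);
    * betweenness centrality: unnormalized count of shortest paths through
      the node, with ties split fractionally (Brandes accumulation).
    """
    w = graph.weights
    n = graph.n_nodes
    out = pd.DataFrame(
        np.zeros((n, len(METRIC_NAMES))), index=list(graph.nodes), columns=list(METRIC_NAMES)
    )
    if n == 0:
        return out
    adj = w > 0
    out["degree"] = adj.sum(axis=1).astype(float)
    out["strength"] = w.sum(axis=1)

    dist = weighted_shortest_paths(graph)
    out["global_efficiency"] = _efficiency_from_distances(dist)

    # local efficiency on neighbor-induced subgraphs
    loc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        sub_dist = dijkstra(csr_matrix(_length_matrix(sub)), directed=False)
        loc[i] = _efficiency_from_distances(sub_dist).mean()
    out["local_efficiency"] = loc

    # Onnela clustering: weights rescaled by the maximum weight in the network
    wmax = w.max()
    if wmax > 0:
        cube = np.cbrt(w / wmax)
        tri = np.diag(cube @ cube @ cube)  # 2x the geometric triangle intensity per node
        k = out["degree"].to_numpy()
        denom = k * (k - 1)
        cc = np.divide(tri, denom, out=np.zeros(n), where=denom > 0)
        out["clustering_coefficient"] = cc

    out["betweenness_centrality"] = _betweenness(w)
    return out


def _betweenness(w: np.ndarray) -> np.ndarray:
    """Weighted betweenness (lengths 1/weight) via igraph's Brandes
    implementation; each unordered pair is counted once, unnormalized."""
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, 1))
    if iu.size == 0:
        return np.zeros(n)
    g = ig.Graph(n=n, edges=list(zip(iu.tolist(), ju.tolist())), directed=False)
    lengths = (1.0 / w[iu, ju]).tolist()
    return np.asarray(g.betweenness(weights=lengths, directed=False), dtype=float)
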