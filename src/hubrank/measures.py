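"""Five node-level graph measures on a single connectome.

Definitions (all topological measures are computed on the binarized graph;
only strength uses the weights):

- degree: number of incident edges.
- strength: total weight of incident edges.
- coreness: largest k such that the node survives iterative removal of all
  nodes with degree < k (k-core decomposition).
- betweenness: fraction of unweighted shortest paths between all other node
  pairs that pass through the node (endpoints excluded), i.e. the Brandes
  pair sum divided by (n-1)(n-2)/2, so values lie in [0, 1].
- closeness: reciprocal of the sum of unweighted shortest-path distances to
  all other nodes.  On disconnected graphs the sum runs over the node's
  reachable set and the reciprocal is scaled by (r-1)/(n-1) (Wasserman-Faust
  component scaling, r = reachable-set size); isolated nodes get 0.

The heavy lifting (Brandes betweenness, k-core) is delegated to igraph's C
implementations; BFS distance matrices come from scipy.sparse.csgraph.
"""

from __future__ import annotations

import warnings

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import ConnectivityMatrix

__all__ = [
    "degree_strength",
    "coreness",
    "betweenness",
    "closeness",
    "measure_all",
]


def _binary(matrix: ConnectivityMatrix) -> np.ndarray:
    return (matrix.weights > 0)


def _graph(adj: np.ndarray) -> ig.Graph:
    edges = np.argwhere(np.triu(adj, k=1))
    return ig.Graph(n=adj.shape[0], edges=edges.tolist())


def degree_strength(matrix: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Degree (binary incident-edge count) and strength (incident weight sum)."""
    adj = _binary(matrix)
    return adj.sum(axis=1).astype(float), matrix.weights.sum(axis=1)


def coreness(matrix: ConnectivityMatrix) -> np.ndarray:
    """k-core number per node of the binarized graph."""
    adj = _binary(matrix)
    return np.asarray(_graph(adj).coreness(mode="all"), dtype=float)


def betweenness(matrix: ConnectivityMatrix) -> np.ndarray:
    """Shortest-path betweenness as a fraction of eligible pairs, in [0, 1]."""
    adj = _binary(matrix)
    n = adj.shape[0]
    if n < 3:
        return np.zeros(n)
    raw = np.asarray(_graph(adj).betweenness(directed=False), dtype=float)
    return raw / ((n - 1) * (n - 2) / 2.0)


def closeness(matrix: ConnectivityMatrix) -> np.ndarray:
    """Reciprocal summed BFS distance, component-scaled when disconnected."""
    adj = _binary(matrix)
    n = adj.shape[0]
    if n == 1:
        return np.zeros(1)
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True)
    finite = np.isfinite(dist)
    reach = finite.sum(axis=1)  # includes the node itself (distance 0)
    dsum = np.where(finite, dist, 0.0).sum(axis=1)
    if np.any(reach < n):
        warnings.warn(
            "graph is disconnected; closeness uses reachable-set scaling",
            stacklevel=2,
        )
    out = np.zeros(n)
    ok = dsum > 0
    out[ok] = (1.0 / dsum[ok]) * ((reach[ok] - 1) / (n - 1))
    return out


def measure_all(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """All five measures as a per-node table (index = node ids).

    Strength is computed on the weighted graph, everything else on the
    binarized graph, matching the measure definitions.
    """
    deg, stren = degree_strength(matrix)
    table = pd.DataFrame(
        {
            "degree": deg,
            "strength": stren,
            "coreness": coreness(matrix),
            "betweenness": betweenness(matrix),
            "closeness": closeness(matrix),
        },
        index=pd.Index(matrix.node_ids, name="roi_id"),
    )
    return table
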