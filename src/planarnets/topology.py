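"""Purely topological graph metrics.

All measures here ignore node coordinates: mean degree <k> = 2M/N, average
clustering coefficient C, alpha index (meshedness) alpha = (M-N+1)/(2N-5),
topological efficiency E^t, and topological edge betweenness centrality.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import shortest_path

from ._betweenness import edge_betweenness
from .network import SpatialNetwork


def mean_degree(net: SpatialNetwork) -> float:
    return 2 * net.n_edges / net.n_nodes


def clustering_coefficient(net: SpatialNetwork) -> float:
    """Average local clustering; nodes of degree < 2 contribute 0."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from(map(tuple, net.edges))
    return nx.average_clustering(g)


def alpha_index(net: SpatialNetwork) -> float:
    """Meshedness of a connected planar graph: 0 for trees, 1 for maximal planar."""
    n, m = net.n_nodes, net.n_edges
    if n < 3:
        raise ValueError("alpha index requires N >= 3")
    return (m - n + 1) / (2 * n - 5)


def topological_shortest_paths(net: SpatialNetwork) -> np.ndarray:
    """Hop-count shortest path length matrix; unreachable pairs are inf."""
    return shortest_path(net.adjacency(), method="D", unweighted=True, directed=False)


def topological_efficiency(net: SpatialNetwork, paths: np.ndarray | None = None) -> float:
    """E^t = mean over ordered pairs of 1/l^t; unreachable pairs contribute 0."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("efficiency requires N >= 2")
    l = topological_shortest_paths(net) if paths is None else paths
    with np.errstate(divide="ignore"):
        inv = 1.0 / l
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def topological_edge_betweenness(net: SpatialNetwork) -> dict[tuple[int, int], float]:
    """Unordered-pair shortest-path counts per edge, ties split fractionally.

    Each node pair {q, r} contributes, to every edge, the fraction of shortest
    hop-count q-r paths traversing that edge; the pair is counted once.
    """
    values = edge_betweenness(
        net.n_nodes, net.edges, np.ones(net.n_edges), tol=0.0
    )
    return {(int(i), int(j)): float(v) for (i, j), v in zip(net.edges, values)}
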