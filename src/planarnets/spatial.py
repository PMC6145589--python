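"""Spatially-embedded network measures.

Wiring length W = sum of Euclidean edge lengths (material-cost proxy),
physical efficiency based on shortest summed-edge-length paths, physical edge
betweenness, and the Spearman rank correlation between the topological and
physical betweenness variants.  Flow is assumed bidirectional (undirected
shortest paths) and edges straight (tortuosity neglected).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import dijkstra

from ._betweenness import edge_betweenness
from .network import SpatialNetwork, distance_matrix


def wiring_length(net: SpatialNetwork, D: np.ndarray | None = None) -> float:
    """W = sum_{i>j} A_ij D_ij."""
    if D is not None:
        return float(D[net.edges[:, 0], net.edges[:, 1]].sum())
    return float(net.edge_lengths().sum())


def physical_shortest_paths(net: SpatialNetwork) -> np.ndarray:
    """Matrix of minimal summed-Euclidean-edge-length path distances."""
    return dijkstra(net.adjacency(weighted=True), directed=False)


def physical_efficiency(
    net: SpatialNetwork,
    D: np.ndarray | None = None,
    paths: np.ndarray | None = None,
) -> tuple[float, float]:
    """Return ``(E^p_avg, E^p)``.

    ``E^p_avg`` is the mean over ordered pairs of the inverse shortest
    physical path length (unreachable pairs contribute 0).  ``E^p`` divides by
    the same quantity for the fully connected network on the same node
    positions (inverse straight-line distances), so ``0 <= E^p <= 1``.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("efficiency requires N >= 2")
    if D is None:
        D = distance_matrix(net)
    l = physical_shortest_paths(net) if paths is None else paths
    with np.errstate(divide="ignore"):
        inv = 1.0 / l
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    e_avg = float(inv.sum() / (n * (n - 1)))
    off = ~np.eye(n, dtype=bool)
    if (D[off] == 0).any():
        raise ValueError("coincident nodes: complete-graph normalisation undefined")
    e_full = float((1.0 / D[off]).sum() / (n * (n - 1)))
    return e_avg, e_avg / e_full


def physical_edge_betweenness(
    net: SpatialNetwork, tol: float = 1e-9
) -> dict[tuple[int, int], float]:
    """Per-edge fraction of minimal-Euclidean-length paths, unordered pairs.

    Geometric ties (path lengths equal to within ``tol`` relative) are split
    fractionally, so lattice fixtures with exactly equal alternative routes
    get symmetric values.
    """
    values = edge_betweenness(net.n_nodes, net.edges, net.edge_lengths(), tol=tol)
    return {(int(i), int(j)): float(v) for (i, j), v in zip(net.edges, values)}


def betweenness_rank_correlation(
    bet_topological: dict[tuple[int, int], float],
    bet_physical: dict[tuple[int, int], float],
) -> float:
    """Spearman rho between the two edge-betweenness maps (average ranks on ties).

    Returns NaN (with a warning) when either map has zero variance.
    """
    if set(bet_topological) != set(bet_physical):
        raise ValueError("betweenness maps must share an identical edge set")
    keys = sorted(bet_topological)
    if len(keys) < 3:
        raise ValueError("need at least 3 edges")
    x = np.array([bet_topological[k] for k in keys])
    y = np.array([bet_physical[k] for k in keys])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in edge betweenness; rho undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
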