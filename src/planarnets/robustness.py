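"""Structural robustness under random edge removal.

Two experiments:

* the robustness statistic ``R`` — the percentage of edges removed, along a
  uniformly random removal order, at which the largest connected component
  (LCC) first drops below half the node count;
* the efficiency-decline curve — the ensemble mean of
  ``E^p(f) / E^p(0)`` as a fraction ``f`` of edges is removed at random,
  whose initial slope (``f`` in [0, 0.1]) summarises how quickly transport
  capability degrades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import SpatialNetwork


@dataclass
class RobustnessResult:
    R_mean: float  # percent of edges removed at LCC halving
    R_sd: float
    trials: int
    seed: int | None
    per_trial: np.ndarray


@dataclass
class DeclineCurve:
    f_grid: np.ndarray
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray
    trials: int
    seed: int | None
    n_sources: int | None = None


def _lcc_halving_count(edges: np.ndarray, n_nodes: int, order: np.ndarray) -> int:
    """First k (number of removed edges) at which LCC < n/2, for one removal order.

    Computed backwards: edges are *added* in reverse removal order under a
    union-find, tracking the largest component; the LCC after removing k
    edges equals the largest component once the last M-k edges are present.
    """
    m = len(edges)
    parent = np.arange(n_nodes)
    size = np.ones(n_nodes, dtype=np.int64)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    threshold = n_nodes / 2.0
    largest = 1
    if largest >= threshold:
        # n_nodes <= 2: a single node is already half the network
        return 0 if n_nodes <= 1 else _small_case(edges, n_nodes, order)
    rev = order[::-1]
    for j, eidx in enumerate(rev):
        u, v = edges[eidx]
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            if size[ru] < size[rv]:
                ru, rv = rv, ru
            parent[rv] = ru
            size[ru] += size[rv]
            if size[ru] > largest:
                largest = int(size[ru])
        if largest >= threshold:
            # with j+1 edges added (the last j+1 in removal order), LCC >= n/2;
            # removing m-(j+1) edges keeps LCC >= n/2, so halving needs one more
            return m - (j + 1) + 1
    return 1  # even the full network is below half (cannot happen if connected)


def _small_case(edges, n_nodes, order) -> int:
    # n_nodes == 2: LCC < 1 is impossible; LCC < N/2 = 1 never holds, but the
    # full removal leaves singletons of size 1 == N/2, not < N/2. Strictness
    # makes R undefined; treat full removal as the halving point.
    return len(edges)


def robustness_R(
    net: SpatialNetwork, trials: int = 20, seed: int | None = None
) -> RobustnessResult:
    """Percentage of randomly removed edges at which the LCC first falls
    below N/2 (strict), averaged over removal-order trials."""
    if net.n_nodes < 2:
        raise ValueError("robustness needs N >= 2")
    rng = np.random.default_rng(seed)
    m = net.n_edges
    vals = np.empty(trials)
    for t in range(trials):
        order = rng.permutation(m)
        k = _lcc_halving_count(net.edges, net.n_nodes, order)
        vals[t] = 100.0 * k / m
    return RobustnessResult(
        R_mean=float(vals.mean()),
        R_sd=float(vals.std(ddof=1)) if trials > 1 else 0.0,
        trials=trials,
        seed=seed,
        per_trial=vals,
    )


def _efficiency_sum(
    n: int, edges: np.ndarray, lengths: np.ndarray, keep: np.ndarray,
    sources: np.ndarray | None,
) -> float:
    """Sum over (sampled) ordered pairs of inverse shortest physical path length."""
    e = edges[keep]
    w = lengths[keep]
    if len(e) == 0:
        return 0.0
    g = csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    if sources is None:
        d = dijkstra(g, directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        return float(inv.sum())
    d = dijkstra(g, directed=False, indices=sources)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    inv[np.arange(len(sources)), sources] = 0.0
    return float(inv.sum())


def efficiency_decline(
    net: SpatialNetwork,
    f_max: float = 0.6,
    df: float = 0.004,
    trials: int = 20,
    seed: int | None = None,
    n_sources: int | None = None,
    nested: bool = False,
) -> DeclineCurve:
    """Mean ratio E^p(f)/E^p(0) on the removal-fraction grid f = 0..f_max.

    For each f and trial an independent uniformly random subset of
    ``floor(f*M)`` edges is removed (set ``nested=True`` to instead truncate
    one random permutation per trial).  Unreachable pairs contribute zero
    efficiency.  ``n_sources`` switches the inverse-path-length sums to a
    fixed random subset of source nodes — an unbiased estimator of the
    ordered-pair mean that makes large ensembles affordable; the f = 0
    denominator uses the same subset, so the ratio at f = 0 is exactly 1.
    """
    if net.n_nodes < 2:
        raise ValueError("decline needs N >= 2")
    rng = np.random.default_rng(seed)
    m = net.n_edges
    edges = net.edges
    lengths = net.edge_lengths()
    n = net.n_nodes
    f_grid = np.arange(0.0, f_max + 0.5 * df, df)
    sources = None
    if n_sources is not None and n_sources < n:
        sources = np.sort(rng.choice(n, size=n_sources, replace=False))
    e0 = _efficiency_sum(n, edges, lengths, np.ones(m, dtype=bool), sources)
    if e0 <= 0:
        raise ValueError("E^p(0) must be positive")
    ratios = np.empty((trials, len(f_grid)))
    for t in range(trials):
        perm = rng.permutation(m) if nested else None
        for k, f in enumerate(f_grid):
            n_remove = int(np.floor(f * m))
            if n_remove == 0:
                ratios[t, k] = 1.0
                continue
            keep = np.ones(m, dtype=bool)
            if nested:
                keep[perm[:n_remove]] = False
            else:
                keep[rng.choice(m, size=n_remove, replace=False)] = False
            ratios[t, k] = _efficiency_sum(n, edges, lengths, keep, sources) / e0
    return DeclineCurve(
        f_grid=f_grid,
        mean_ratio=ratios.mean(axis=0),
        sd_ratio=ratios.std(axis=0, ddof=1) if trials > 1 else np.zeros(len(f_grid)),
        trials=trials,
        seed=seed,
        n_sources=n_sources,
    )


def decline_slope(curve: DeclineCurve, f_upper: float = 0.1) -> float:
    """OLS slope of <E^p(f)/E^p(0)> vs f over f in [0, f_upper]."""
    sel = curve.f_grid <= f_upper + 1e-12
    if sel.sum() < 3:
        raise ValueError("need at least 3 grid points below f_upper")
    res = stats.linregress(curve.f_grid[sel], curve.mean_ratio[sel])
    return float(res.slope)
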