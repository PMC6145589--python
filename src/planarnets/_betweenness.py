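"""Edge betweenness by Brandes' accumulation over Dijkstra trees.

Path lengths are summed edge weights (hop counts when all weights are 1).
Two path lengths tie when they differ by less than ``tol`` relative (exact
equality when ``tol=0``); tied predecessors split the pair's contribution
fractionally.  The relative tolerance matters for geometric weights, where
equal-length alternative routes (e.g. around a lattice cell) accumulate
floating-point error.

Returns one value per input edge under the unordered-pair convention: each
node pair {q, r} is counted once.
"""

from __future__ import annotations

import heapq

import numpy as np


def edge_betweenness(
    n_nodes: int, edges: np.ndarray, weights: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    m = len(edges)
    bet = np.zeros(m)
    if m == 0 or n_nodes < 2:
        return bet
    # CSR-style adjacency with edge ids
    deg = np.zeros(n_nodes, dtype=np.int64)
    np.add.at(deg, edges.ravel(), 1)
    ptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(deg, out=ptr[1:])
    nbr = np.empty(2 * m, dtype=np.int64)
    eid = np.empty(2 * m, dtype=np.int64)
    fill = ptr[:-1].copy()
    for k in range(m):
        i, j = edges[k]
        nbr[fill[i]] = j
        eid[fill[i]] = k
        fill[i] += 1
        nbr[fill[j]] = i
        eid[fill[j]] = k
        fill[j] += 1
    w = np.asarray(weights, dtype=float)

    for s in range(n_nodes):
        dist = np.full(n_nodes, np.inf)
        sigma = np.zeros(n_nodes)
        preds: list[list[tuple[int, int]]] = [[] for _ in range(n_nodes)]
        done = np.zeros(n_nodes, dtype=bool)
        dist[s] = 0.0
        sigma[s] = 1.0
        heap = [(0.0, s)]
        order = []
        while heap:
            d, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for k in range(ptr[u], ptr[u + 1]):
                v = nbr[k]
                if done[v]:
                    continue
                nd = d + w[eid[k]]
                slack = tol * max(1.0, nd)
                if nd < dist[v] - slack:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [(u, eid[k])]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - dist[v]) <= slack:
                    sigma[v] += sigma[u]
                    preds[v].append((u, eid[k]))
        delta = np.zeros(n_nodes)
        for v in reversed(order):
            coeff = (1.0 + delta[v]) / sigma[v]
            for u, e in preds[v]:
                c = sigma[u] * coeff
                bet[e] += c
                delta[u] += c
    return bet / 2.0  # each unordered pair was counted from both endpoints
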