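"""Reference constructions for spatial networks.

Three null models, each sharing the source network's node positions:

* Euclidean minimum spanning tree (MST) — the minimally wired connected
  planar graph on the node positions; lower anchor for cost/efficiency/
  robustness.
* Greedy triangulation (GT) — node pairs connected in ascending order of
  Euclidean distance whenever the new straight edge crosses no accepted edge;
  a maximal planar graph and the upper anchor.
* Connected degree-preserving rewiring — double-edge swaps that keep the
  degree sequence, simplicity and connectedness; the topological benchmark
  behind the X / <X_rewire> normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as _csgraph_mst
from scipy.spatial import ConvexHull, QhullError

from .generators import delaunay_edges
from .network import SpatialNetwork, canonical_edges


@dataclass
class NullEnsemble:
    kind: str
    members: list[SpatialNetwork]
    source_name: str = ""
    seeds: list[int] = field(default_factory=list)
    accepted_swaps: list[int] = field(default_factory=list)
    attempts: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _as_network(coords_or_net, name: str) -> SpatialNetwork:
    if isinstance(coords_or_net, SpatialNetwork):
        return coords_or_net
    coords = np.asarray(coords_or_net, dtype=float)
    return SpatialNetwork(
        node_ids=[f"n{i}" for i in range(len(coords))],
        coords=coords,
        edges=np.zeros((0, 2), dtype=np.int64),
        name=name,
    )


# -- Euclidean MST ------------------------------------------------------------

def euclidean_mst(coords_or_net) -> SpatialNetwork:
    """Spanning tree of minimal total Euclidean length on the node positions.

    Computed on the Delaunay-triangulation edge set (a superset of the
    Euclidean MST) for near-linear scaling; degenerate inputs fall back to the
    complete pair list.
    """
    src = _as_network(coords_or_net, "points")
    coords = src.coords
    n = len(coords)
    if n < 2:
        raise ValueError("MST needs at least 2 nodes")
    if len(np.unique(coords, axis=0)) < n:
        raise ValueError("coincident points: MST undefined")
    if n == 2:
        cand = np.array([[0, 1]], dtype=np.int64)
    else:
        try:
            cand = delaunay_edges(coords)
        except QhullError:  # collinear input: chain along the line
            order = np.lexsort((coords[:, 1], coords[:, 0]))
            cand = np.column_stack([order[:-1], order[1:]])
    w = np.linalg.norm(coords[cand[:, 0]] - coords[cand[:, 1]], axis=1)
    g = csr_matrix((w, (cand[:, 0], cand[:, 1])), shape=(n, n))
    t = _csgraph_mst(g).tocoo()
    edges = canonical_edges(np.column_stack([t.row, t.col]))
    assert len(edges) == n - 1
    return src.with_edges(edges, name=f"{src.name}.mst" if src.name else "mst")


# -- Greedy triangulation -----------------------------------------------------

@njit(cache=True)
def _segments_cross_scalar(px, py, qx, qy, ax, ay, bx, by):  # pragma: no cover
    rx, ry = qx - px, qy - py
    sx, sy = bx - ax, by - ay
    qpx, qpy = ax - px, ay - py
    rxs = rx * sy - ry * sx
    qpxr = qpx * ry - qpy * rx
    if rxs != 0.0:
        t = (qpx * sy - qpy * sx) / rxs
        u = qpxr / rxs
        eps = 1e-12
        return (t > eps) and (t < 1 - eps) and (u > eps) and (u < 1 - eps)
    if qpxr != 0.0:
        return False
    rr = rx * rx + ry * ry
    if rr == 0.0:
        return False
    t0 = (qpx * rx + qpy * ry) / rr
    t1 = t0 + (sx * rx + sy * ry) / rr
    lo = min(t0, t1)
    hi = max(t0, t1)
    return (min(hi, 1.0) - max(lo, 0.0)) > 1e-12


@njit(cache=True)
def _gt_kernel(coords, pi, pj, quota, ox, oy, cell, gx, gy, cap):  # pragma: no cover
    """Greedy insertion over (distance, i, j)-sorted pairs with a uniform-grid
    crossing index.  Returns (edge array, n_edges, overflow_flag)."""
    head = np.full(gx * gy, -1, dtype=np.int64)
    nxt = np.empty(cap, dtype=np.int64)
    ent = np.empty(cap, dtype=np.int64)
    n_ent = 0
    out = np.empty((quota, 2), dtype=np.int64)
    e1 = np.empty((quota, 2))
    e2 = np.empty((quota, 2))
    seen = np.full(quota, -1, dtype=np.int64)
    ne = 0
    for t in range(len(pi)):
        i = pi[t]
        j = pj[t]
        px, py = coords[i, 0], coords[i, 1]
        qx, qy = coords[j, 0], coords[j, 1]
        seglen = np.sqrt((qx - px) ** 2 + (qy - py) ** 2)
        nstep = int(seglen / (0.5 * cell)) + 1
        crossed = False
        for k in range(nstep + 1):
            f = k / nstep
            sx = px + f * (qx - px)
            sy = py + f * (qy - py)
            cx = int((sx - ox) / cell)
            cy = int((sy - oy) / cell)
            if cx < 0:
                cx = 0
            if cx >= gx:
                cx = gx - 1
            if cy < 0:
                cy = 0
            if cy >= gy:
                cy = gy - 1
            e = head[cx * gy + cy]
            while e != -1:
                eidx = ent[e]
                if seen[eidx] != t:
                    seen[eidx] = t
                    if _segments_cross_scalar(
                        px, py, qx, qy, e1[eidx, 0], e1[eidx, 1], e2[eidx, 0], e2[eidx, 1]
                    ):
                        crossed = True
                        break
                e = nxt[e]
            if crossed:
                break
        if crossed:
            continue
        # accept: register into padded (3x3) cells along the segment
        out[ne, 0] = i
        out[ne, 1] = j
        e1[ne, 0], e1[ne, 1] = px, py
        e2[ne, 0], e2[ne, 1] = qx, qy
        for k in range(nstep + 1):
            f = k / nstep
            sx = px + f * (qx - px)
            sy = py + f * (qy - py)
            cx0 = int((sx - ox) / cell)
            cy0 = int((sy - oy) / cell)
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    cx = cx0 + dx
                    cy = cy0 + dy
                    if cx < 0 or cx >= gx or cy < 0 or cy >= gy:
                        continue
                    c = cx * gy + cy
                    # avoid duplicate registration in this cell for this edge
                    e = head[c]
                    dup = False
                    while e != -1:
                        if ent[e] == ne:
                            dup = True
                            break
                        e = nxt[e]
                    if dup:
                        continue
                    if n_ent >= cap:
                        return out, ne, 1
                    nxt[n_ent] = head[c]
                    ent[n_ent] = ne
                    head[c] = n_ent
                    n_ent += 1
        ne += 1
        if ne >= quota:
            break
    return out, ne, 0


def greedy_triangulation(coords_or_net, max_nodes: int = 4000) -> SpatialNetwork:
    """Maximal non-crossing straight-line graph by ascending pair distance.

    Ties in distance are broken deterministically by (smaller id, larger id).
    For points in general position the result is a triangulation with exactly
    ``3N - 3 - h`` edges (h = convex hull vertices).  All-collinear input
    degenerates to the chain, with a warning.
    """
    src = _as_network(coords_or_net, "points")
    coords = np.asarray(src.coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise ValueError("greedy triangulation needs at least 3 nodes")
    if n > max_nodes:
        raise ValueError(f"N={n} exceeds max_nodes={max_nodes} (quadratic pair list)")
    if len(np.unique(coords, axis=0)) < n:
        raise ValueError("coincident points")
    name = f"{src.name}.gt" if src.name else "gt"
    try:
        hull = ConvexHull(coords)
        n_hull = len(hull.vertices)
    except QhullError:
        warnings.warn("all points collinear: greedy triangulation degenerates to chain",
                      stacklevel=2)
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        edges = canonical_edges(np.column_stack([order[:-1], order[1:]]))
        return src.with_edges(edges, name=name)
    quota = 3 * n - 3 - n_hull
    pi, pj = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[pi] - coords[pj], axis=1)
    order = np.lexsort((pj, pi, d))
    pi, pj = pi[order].astype(np.int64), pj[order].astype(np.int64)
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    cell = float(max(np.sqrt(max(span[0] * span[1], 1e-300) / n), 1e-12))
    gx = int(span[0] / cell) + 1
    gy = int(span[1] / cell) + 1
    cap = 64 * quota + 4096
    for _ in range(4):
        edges, ne, overflow = _gt_kernel(
            coords, pi, pj, quota, float(lo[0]), float(lo[1]), cell, gx, gy, cap
        )
        if not overflow:
            break
        cap *= 4
    else:  # pragma: no cover
        raise RuntimeError("greedy triangulation grid overflow")
    return src.with_edges(canonical_edges(edges[:ne]), name=name)


# -- Connected degree-preserving rewiring ------------------------------------

def _is_unswappable(edges: np.ndarray, n_nodes: int) -> bool:
    """No double-edge swap exists when every edge shares a common node (star)."""
    if len(edges) < 2:
        return True
    deg = np.zeros(n_nodes, dtype=np.int64)
    np.add.at(deg, edges.ravel(), 1)
    return bool(deg.max() == len(edges))


def _rewire_once(
    edges: np.ndarray, n_nodes: int, n_target: int, attempt_cap: int, rng: np.random.Generator
) -> tuple[np.ndarray, int, int]:
    """Windowed connected double-edge swap on one member.

    Swaps are applied blindly in windows; connectivity is re-checked per
    window and the window rolled back (and shrunk) on failure, which keeps the
    per-swap cost amortised well below one BFS.
    """
    adj: list[set[int]] = [set() for _ in range(n_nodes)]
    elist: list[tuple[int, int]] = []
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
        elist.append((int(u), int(v)))
    m = len(elist)

    def connected() -> bool:
        seen = np.zeros(n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    count += 1
                    stack.append(v)
        return count == n_nodes

    def apply_swap(k1: int, k2: int, flip: bool) -> bool:
        u, v = elist[k1]
        x, y = elist[k2]
        if flip:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            return False
        if x in adj[u] or y in adj[v]:
            return False
        adj[u].remove(v); adj[v].remove(u)
        adj[x].remove(y); adj[y].remove(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        elist[k1] = (u, x)
        elist[k2] = (v, y)
        return True

    def undo(k1: int, k2: int, before1, before2) -> None:
        (u, x), (v, y) = elist[k1], elist[k2]
        adj[u].remove(x); adj[x].remove(u)
        adj[v].remove(y); adj[y].remove(v)
        a, b = before1
        c, d = before2
        adj[a].add(b); adj[b].add(a)
        adj[c].add(d); adj[d].add(c)
        elist[k1] = before1
        elist[k2] = before2

    swaps = 0
    attempts = 0
    window = 1
    while swaps < n_target and attempts < attempt_cap:
        performed: list[tuple[int, int, tuple, tuple]] = []
        while len(performed) < window and attempts < attempt_cap:
            attempts += 1
            k1, k2 = rng.integers(0, m, size=2)
            if k1 == k2:
                continue
            before1, before2 = elist[k1], elist[k2]
            if apply_swap(int(k1), int(k2), bool(rng.integers(0, 2))):
                performed.append((int(k1), int(k2), before1, before2))
        if not performed:
            break
        if connected():
            swaps += len(performed)
            window = min(window * 2, max(1, n_target - swaps))
        else:
            for k1, k2, b1, b2 in reversed(performed):
                undo(k1, k2, b1, b2)
            window = max(1, window // 2)
    return canonical_edges(np.array(elist, dtype=np.int64)), swaps, attempts


def degree_preserving_rewire(
    net: SpatialNetwork,
    n_members: int = 10,
    swaps_per_edge: int = 15,
    seed: int | None = None,
) -> NullEnsemble:
    """Ensemble of connected, degree-sequence-preserving rewirings.

    Targets ``swaps_per_edge * M`` *accepted* swaps per member with an attempt
    cap of ``100 * M``; members with no valid swap (e.g. stars) are returned
    equal to the source and flagged.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    master = np.random.default_rng(seed)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_members)]
    members, flags, swaps_done, attempts_done = [], [], [], []
    unswappable = _is_unswappable(net.edges, net.n_nodes)
    for k, s in enumerate(seeds):
        suffix = f".rewire-{k:02d}"
        if unswappable:
            members.append(net.with_edges(net.edges.copy(), name=net.name + suffix))
            flags.append("no valid swap: member equals source")
            swaps_done.append(0)
            attempts_done.append(0)
            continue
        rng = np.random.default_rng(s)
        edges, nswaps, natt = _rewire_once(
            net.edges, net.n_nodes, swaps_per_edge * net.n_edges,
            100 * net.n_edges, rng,
        )
        member = net.with_edges(edges, name=net.name + suffix)
        assert np.array_equal(np.sort(member.degrees()), np.sort(net.degrees()))
        assert member.is_connected()
        members.append(member)
        flags.append("")
        swaps_done.append(nswaps)
        attempts_done.append(natt)
    return NullEnsemble(
        kind="rewired",
        members=members,
        source_name=net.name,
        seeds=seeds,
        accepted_swaps=swaps_done,
        attempts=attempts_done,
        flags=flags,
    )


def ensemble_normalize(x: float, ensemble_values) -> tuple[float, float, float]:
    """Return ``(x / <X_rewire>, ensemble mean, ensemble sd)``.

    A zero ensemble mean (common for clustering in rewired nulls, where
    triangles are rare) yields NaN with a warning rather than infinity.
    """
    vals = np.asarray(list(ensemble_values), dtype=float)
    if len(vals) == 0:
        raise ValueError("empty ensemble")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if mean == 0:
        warnings.warn("ensemble mean is 0; normalised value undefined", stacklevel=2)
        return float("nan"), mean, sd
    return x / mean, mean, sd
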