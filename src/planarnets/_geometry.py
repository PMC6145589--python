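"""Segment-intersection predicates shared by the null models and generators.

Crossing semantics (straight-line planarity): a *proper* interior intersection
of the two open segments counts as a crossing; a shared endpoint does not;
collinear overlap of positive length does.
"""

from __future__ import annotations

import numpy as np


def segments_cross(p: np.ndarray, q: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Does segment ``p-q`` cross each of the segments ``a[k]-b[k]``? (vectorized)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    r = q - p
    s = b - a
    qp = a - p
    rxs = r[0] * s[:, 1] - r[1] * s[:, 0]
    qpxr = qp[:, 0] * r[1] - qp[:, 1] * r[0]
    out = np.zeros(len(a), dtype=bool)
    nz = rxs != 0
    if nz.any():
        t = (qp[nz, 0] * s[nz, 1] - qp[nz, 1] * s[nz, 0]) / rxs[nz]
        u = qpxr[nz] / rxs[nz]
        eps = 1e-12
        out[nz] = (t > eps) & (t < 1 - eps) & (u > eps) & (u < 1 - eps)
    co = (~nz) & (qpxr == 0)  # parallel and collinear
    if co.any():
        rr = float(r @ r)
        if rr == 0:
            return out
        t0 = (qp[co] @ r) / rr
        t1 = t0 + (s[co] @ r) / rr
        lo = np.minimum(t0, t1)
        hi = np.maximum(t0, t1)
        out[co] = (np.minimum(hi, 1.0) - np.maximum(lo, 0.0)) > 1e-12
    return out


def count_crossings(coords: np.ndarray, edges: np.ndarray) -> int:
    """Brute-force count of crossing edge pairs (planarity check for small nets)."""
    n_cross = 0
    a = coords[edges[:, 0]]
    b = coords[edges[:, 1]]
    for k in range(len(edges) - 1):
        i, j = edges[k]
        later = edges[k + 1 :]
        hit = segments_cross(a[k], b[k], a[k + 1 :], b[k + 1 :])
        # shared-endpoint pairs are handled by the proper-crossing predicate
        # except for collinear overlap, which genuinely is non-planar
        shares = (
            (later[:, 0] == i) | (later[:, 1] == i) | (later[:, 0] == j) | (later[:, 1] == j)
        )
        coll = _collinear_with(coords, i, j, later)
        n_cross += int(np.sum(hit & (~shares | coll)))
    return n_cross


def _collinear_with(coords, i, j, others):
    p, q = coords[i], coords[j]
    r = q - p
    c1 = r[0] * (coords[others[:, 0], 1] - p[1]) - r[1] * (coords[others[:, 0], 0] - p[0])
    c2 = r[0] * (coords[others[:, 1], 1] - p[1]) - r[1] * (coords[others[:, 1], 0] - p[0])
    return (c1 == 0) & (c2 == 0)


def is_planar_embedding(coords: np.ndarray, edges: np.ndarray) -> bool:
    return count_crossings(np.asarray(coords, float), np.asarray(edges)) == 0
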