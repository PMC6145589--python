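"""Relative measures against the spatial null models and two-group statistics.

The relative quantities rescale an empirical value between its Euclidean-MST
counterpart (0) and its greedy-triangulation counterpart (1) on the same node
positions:

    W_rel   = (W - W_MST) / (W_GT - W_MST)
    E^p_rel = (E^p - E^p_MST) / (E^p_GT - E^p_MST)
    R_rel   = (R - R_MST) / (R_GT - R_MST)

Group comparisons use a two-sided two-sample t-test (pooled-variance Student
test by default, Welch optionally) with means reported +- standard error of
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import SpatialNetwork, distance_matrix
from .nulls import euclidean_mst, greedy_triangulation
from .robustness import robustness_R
from .spatial import physical_efficiency, wiring_length


@dataclass
class RelativeMeasures:
    w_rel: float
    e_p_rel: float
    r_rel: float
    raw: dict = field(default_factory=dict)  # (X, X_MST, X_GT) per measure


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int
    variant: str = "pooled"


def relative_measures(
    net: SpatialNetwork,
    D: np.ndarray | None = None,
    mst: SpatialNetwork | None = None,
    gt: SpatialNetwork | None = None,
    trials: int = 20,
    seed: int | None = None,
) -> RelativeMeasures:
    """W_rel, E^p_rel, R_rel of a network against MST/GT on its node positions.

    The robustness values entering R_rel are trial averages; the three
    networks get independent substreams of ``seed`` so the whole triple is
    reproducible.
    """
    if mst is None:
        mst = euclidean_mst(net)
    if gt is None:
        gt = greedy_triangulation(net)
    if D is None:
        D = distance_matrix(net)
    w = wiring_length(net, D)
    w_mst = wiring_length(mst, D)
    w_gt = wiring_length(gt, D)
    if w_gt == w_mst:
        raise ValueError("degenerate null models: W_GT == W_MST")
    _, ep = physical_efficiency(net, D)
    _, ep_mst = physical_efficiency(mst, D)
    _, ep_gt = physical_efficiency(gt, D)
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=3)
    r = robustness_R(net, trials=trials, seed=int(seeds[0])).R_mean
    r_mst = robustness_R(mst, trials=trials, seed=int(seeds[1])).R_mean
    r_gt = robustness_R(gt, trials=trials, seed=int(seeds[2])).R_mean
    return RelativeMeasures(
        w_rel=(w - w_mst) / (w_gt - w_mst),
        e_p_rel=(ep - ep_mst) / (ep_gt - ep_mst),
        r_rel=(r - r_mst) / (r_gt - r_mst),
        raw={
            "W": (w, w_mst, w_gt),
            "E_p": (ep, ep_mst, ep_gt),
            "R": (r, r_mst, r_gt),
        },
    )


def group_compare(
    values_a,
    values_b,
    metric: str = "",
    variant: str = "pooled",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t-test between two groups of per-network values."""
    a = np.asarray([v for v in values_a if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in values_b if np.isfinite(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if not np.isfinite(t):
        t, p = float("nan"), float("nan")
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(np.isfinite(p) and p < alpha),
        n_a=len(a),
        n_b=len(b),
        variant=variant,
    )


def published_group_rows(variant: str = "pooled") -> dict[str, GroupComparison]:
    """Mean-degree and alpha group rows computed from the published counts.

    These are the two size-derivable rows of the study's summary table; the
    remaining rows need node coordinates and are covered by the synthetic
    cohort analysis instead.
    """
    from .datasets import FUNGI, published_counts

    df = published_counts()
    fun = df[df.group == FUNGI]
    vas = df[df.group != FUNGI]
    return {
        "mean_degree": group_compare(
            fun.mean_degree, vas.mean_degree, metric="mean_degree", variant=variant
        ),
        "alpha": group_compare(fun.alpha, vas.alpha, metric="alpha", variant=variant),
    }
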