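"""Null models against brute-force oracles: MST optimality, GT maximality and
edge-count identity, connected degree-preserving rewiring."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial import ConvexHull

from planarnets.generators import make_fixture
from planarnets.network import SpatialNetwork
from planarnets.nulls import (
    degree_preserving_rewire,
    ensemble_normalize,
    euclidean_mst,
    greedy_triangulation,
)
from planarnets.spatial import wiring_length


def _net_from_points(pts, name="pts"):
    pts = np.asarray(pts, float)
    return SpatialNetwork(
        [f"n{i}" for i in range(len(pts))], pts, np.zeros((0, 2), dtype=np.int64), name=name
    )


def _brute_force_mst_length(pts):
    """Minimum total length over all spanning trees (enumeration)."""
    n = len(pts)
    pairs = list(itertools.combinations(range(n), 2))
    lengths = {p: float(np.linalg.norm(pts[p[0]] - pts[p[1]])) for p in pairs}
    best = np.inf
    for tree in itertools.combinations(pairs, n - 1):
        g = nx.Graph(tree)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = min(best, sum(lengths[e] for e in tree))
    return best


def _cross_naive(p, q, a, b):
    """Independent orientation-based proper-crossing predicate."""
    def orient(u, v, w):
        return (v[0] - u[0]) * (w[1] - u[1]) - (v[1] - u[1]) * (w[0] - u[0])

    o1, o2 = orient(p, q, a), orient(p, q, b)
    o3, o4 = orient(a, b, p), orient(a, b, q)
    return o1 * o2 < 0 and o3 * o4 < 0


class TestEuclideanMST:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_over_all_spanning_trees(self, seed):
        pts = np.random.default_rng(seed).random((6, 2))
        mst = euclidean_mst(_net_from_points(pts))
        assert mst.n_edges == 5
        assert wiring_length(mst) == pytest.approx(_brute_force_mst_length(pts))

    def test_unit_square_length_three(self, square):
        assert wiring_length(euclidean_mst(square)) == pytest.approx(3.0)

    def test_collinear_points_chain(self):
        pts = np.column_stack([np.array([3.0, 0.0, 1.0, 7.0]), np.zeros(4)])
        mst = euclidean_mst(_net_from_points(pts))
        assert mst.n_edges == 3
        assert wiring_length(mst) == pytest.approx(7.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            euclidean_mst(_net_from_points([[0, 0], [0, 0], [1, 1]]))


class TestGreedyTriangulation:
    def test_unit_square_keeps_one_diagonal(self, square):
        gt = greedy_triangulation(square)
        assert gt.n_edges == 5
        edge_set = {tuple(e) for e in gt.edges}
        # tie between the diagonals broken by (distance, smaller id, larger id)
        assert (0, 2) in edge_set and (1, 3) not in edge_set

    def test_three_points_triangle(self):
        gt = greedy_triangulation(_net_from_points([[0, 0], [1, 0], [0.4, 1.0]]))
        assert gt.n_edges == 3

    @pytest.mark.parametrize("n,seed", [(20, 0), (35, 1), (50, 2)])
    def test_edge_count_identity_and_maximality(self, n, seed):
        """|GT| = 3N - 3 - h for points in general position, and no further
        non-crossing edge can be added (brute force)."""
        pts = np.random.default_rng(seed).random((n, 2))
        gt = greedy_triangulation(_net_from_points(pts))
        h = len(ConvexHull(pts).vertices)
        assert gt.n_edges == 3 * n - 3 - h
        present = {tuple(e) for e in gt.edges}
        segs = [(pts[i], pts[j]) for i, j in gt.edges]
        for i, j in itertools.combinations(range(n), 2):
            if (i, j) in present:
                continue
            assert any(_cross_naive(pts[i], pts[j], a, b) for a, b in segs), (
                f"edge ({i},{j}) could still be added"
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_greedy(self, seed):
        """Same edge set as a quadratic reference implementation."""
        pts = np.random.default_rng(100 + seed).random((25, 2))
        order = sorted(
            itertools.combinations(range(25), 2),
            key=lambda p: (np.linalg.norm(pts[p[0]] - pts[p[1]]), p[0], p[1]),
        )
        acc = []
        for i, j in order:
            if not any(_cross_naive(pts[i], pts[j], pts[a], pts[b]) for a, b in acc):
                acc.append((i, j))
        gt = greedy_triangulation(_net_from_points(pts))
        assert {tuple(e) for e in gt.edges} == set(acc)

    def test_collinear_degenerates_to_chain(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.warns(UserWarning, match="collinear"):
            gt = greedy_triangulation(_net_from_points(pts))
        assert gt.n_edges == 4

    def test_sandwich_property(self, mycelium_small):
        """W_MST <= W_net <= W_GT for Delaunay-subset synthetic networks."""
        w = wiring_length(mycelium_small)
        assert wiring_length(euclidean_mst(mycelium_small)) <= w
        assert w <= wiring_length(greedy_triangulation(mycelium_small))


class TestRewiring:
    def test_degree_sequence_and_connectivity_preserved(self, mycelium_small):
        ens = degree_preserving_rewire(mycelium_small, n_members=3, seed=0)
        src_deg = np.sort(mycelium_small.degrees())
        for member in ens.members:
            assert np.array_equal(np.sort(member.degrees()), src_deg)
            assert member.is_connected()
            assert np.array_equal(member.coords, mycelium_small.coords)

    def test_swap_targets_recorded(self, mycelium_small):
        ens = degree_preserving_rewire(mycelium_small, n_members=2, swaps_per_edge=5, seed=1)
        target = 5 * mycelium_small.n_edges
        assert all(s == target for s in ens.accepted_swaps)
        assert all(a <= 100 * mycelium_small.n_edges for a in ens.attempts)

    def test_cycle4_members_isomorphic_to_source(self):
        """The 4-cycle is the only connected simple graph on its degree
        sequence, so every member must again be a 4-cycle."""
        ens = degree_preserving_rewire(make_fixture("cycle", 4), n_members=5, seed=3)
        for member in ens.members:
            assert member.n_edges == 4
            assert np.all(member.degrees() == 2)
            assert member.is_connected()

    def test_star_has_no_valid_swap(self):
        ens = degree_preserving_rewire(make_fixture("star", 6), n_members=3, seed=0)
        assert all("no valid swap" in f for f in ens.flags)
        for member in ens.members:
            assert np.array_equal(member.edges, make_fixture("star", 6).edges)

    def test_determinism(self, mycelium_small):
        a = degree_preserving_rewire(mycelium_small, n_members=2, seed=7)
        b = degree_preserving_rewire(mycelium_small, n_members=2, seed=7)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.edges, mb.edges)


class TestEnsembleNormalize:
    def test_value_equal_to_mean_gives_one(self):
        ratio, mean, sd = ensemble_normalize(2.0, [1.0, 2.0, 3.0])
        assert ratio == pytest.approx(1.0)
        assert mean == pytest.approx(2.0)

    def test_identical_members_zero_sd(self):
        _, _, sd = ensemble_normalize(1.0, [4.0, 4.0, 4.0])
        assert sd == 0.0

    def test_zero_mean_reported_missing(self):
        with pytest.warns(UserWarning, match="ensemble mean is 0"):
            ratio, _, _ = ensemble_normalize(0.5, [0.0, 0.0])
        assert np.isnan(ratio)
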