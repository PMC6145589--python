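"""Core data model: loading, validation, geometry, stub reduction, round trips."""

import io

import numpy as np
import pytest

from planarnets.network import (
    NetworkValidationError,
    SpatialNetwork,
    distance_matrix,
    load_graphml,
    load_network,
    reduce_stubs,
    validate,
    write_graphml,
    write_network,
)

from conftest import random_connected_net


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestLoad:
    def test_unit_square_round_numbers(self):
        net = load_network(
            _csv("id,x,y\na,0,0\nb,1,0\nc,1,1\nd,0,1"),
            _csv("source,target\na,b\nb,c\nc,d\nd,a"),
        )
        assert net.n_nodes == 4 and net.n_edges == 4

    def test_reversed_duplicate_edge_collapses(self):
        net = load_network(
            _csv("id,x,y\na,0,0\nb,1,0"),
            _csv("source,target\na,b\nb,a"),
        )
        assert net.n_edges == 1

    def test_unknown_node_in_edge_table(self):
        with pytest.raises(NetworkValidationError, match="unknown node"):
            load_network(_csv("id,x,y\na,0,0\nb,1,0"), _csv("source,target\na,z"))

    def test_self_loop_rejected(self):
        with pytest.raises(NetworkValidationError):
            load_network(_csv("id,x,y\na,0,0\nb,1,0"), _csv("source,target\na,a\na,b"))

    def test_non_numeric_coordinate(self):
        with pytest.raises(NetworkValidationError, match="non-numeric"):
            load_network(_csv("id,x,y\na,0,zero\nb,1,0"), _csv("source,target\na,b"))

    def test_disconnected_rejected_unless_overridden(self):
        nodes = _csv("id,x,y\na,0,0\nb,1,0\nc,5,5\nd,6,5")
        edges = _csv("source,target\na,b\nc,d")
        with pytest.raises(NetworkValidationError, match="not connected"):
            load_network(nodes, edges)
        nodes.seek(0), edges.seek(0)
        net = load_network(nodes, edges, require_connected=False)
        assert net.n_edges == 2


class TestDistanceMatrix:
    def test_3_4_5_triangle(self):
        net = SpatialNetwork(["a", "b"], [[0, 0], [3, 4]], [[0, 1]])
        assert distance_matrix(net)[0, 1] == 5.0

    def test_duplicate_coordinates_warn(self):
        net = SpatialNetwork(["a", "b", "c"], [[0, 0], [0, 0], [1, 0]], [[0, 2], [1, 2]])
        with pytest.warns(UserWarning, match="duplicate"):
            D = distance_matrix(net)
        assert D[0, 1] == 0.0

    def test_unit_square_distances(self, square):
        D = distance_matrix(square)
        off = sorted(D[np.triu_indices(4, 1)])
        assert np.allclose(off, [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        net = random_connected_net(seed)
        D0 = distance_matrix(net)
        th = np.random.default_rng(seed).uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = SpatialNetwork(net.node_ids, net.coords @ rot.T + [3.7, -1.2], net.edges)
        assert np.allclose(distance_matrix(moved), D0, rtol=1e-9, atol=1e-9)


class TestReduceStubs:
    def _triangle_plus_stub(self):
        return SpatialNetwork(
            ["a", "b", "c", "s"],
            [[0, 0], [1, 0], [0.5, 1], [1.5, 0.5]],
            [[0, 1], [1, 2], [0, 2], [1, 3]],
            node_type=["branch", "branch", "branch", "penetrating_arteriole"],
        )

    def test_triangle_plus_stub(self):
        out = reduce_stubs(self._triangle_plus_stub())
        assert out.n_nodes == 3 and out.n_edges == 3

    def test_unlabelled_network_unchanged(self, grid3):
        assert reduce_stubs(grid3) is grid3

    def test_two_stubs_on_same_backbone_node(self):
        net = SpatialNetwork(
            ["a", "b", "c", "s1", "s2"],
            [[0, 0], [1, 0], [0.5, 1], [2, 0], [1, -1]],
            [[0, 1], [1, 2], [0, 2], [1, 3], [1, 4]],
            node_type=["branch"] * 3 + ["penetrating_arteriole"] * 2,
        )
        out = reduce_stubs(net)
        assert out.n_nodes == 3 and out.n_edges == 3
        # the attachment node lost exactly its two stubs
        assert out.degrees()[out.index_of("b")] == 2

    def test_degree_changes_limited_to_attachment_points(self):
        net = self._triangle_plus_stub()
        before = dict(zip(net.node_ids, net.degrees()))
        out = reduce_stubs(net)
        after = dict(zip(out.node_ids, out.degrees()))
        assert after["a"] == before["a"] and after["c"] == before["c"]
        assert after["b"] == before["b"] - 1


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(4))
    def test_csv_round_trip_exact(self, tmp_path, seed):
        net = random_connected_net(seed)
        npath, epath = write_network(net, tmp_path)
        back = load_network(npath, epath, name=net.name)
        assert back.node_ids == net.node_ids
        assert np.allclose(back.coords, net.coords, rtol=1e-9)
        assert np.array_equal(back.edges, net.edges)
        assert back.node_type == net.node_type

    def test_graphml_round_trip(self, tmp_path, square):
        p = tmp_path / "square.graphml"
        write_graphml(square, p)
        back = load_graphml(p)
        assert np.allclose(back.coords, square.coords)
        assert np.array_equal(back.edges, square.edges)

    def test_single_node_network(self, tmp_path):
        net = SpatialNetwork(["only"], [[0.0, 0.0]], np.zeros((0, 2), dtype=np.int64))
        npath, epath = write_network(net, tmp_path)
        back = load_network(npath, epath)
        assert back.n_nodes == 1 and back.n_edges == 0


def test_validation_report_counts(square):
    rep = validate(square)
    assert rep.connected and rep.n_nodes == 4 and rep.n_edges == 4
    assert rep.n_edges >= rep.n_nodes - 1


def test_zero_length_edge_is_error():
    net = SpatialNetwork(["a", "b", "c"], [[0, 0], [0, 0], [1, 0]], [[0, 1], [1, 2]])
    with pytest.raises(NetworkValidationError, match="zero-length"):
        validate(net)
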