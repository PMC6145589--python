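"""Planar spatial networks: data model, validation, I/O, Euclidean geometry.

A :class:`SpatialNetwork` is an undirected simple graph whose nodes carry 2D
coordinates and an optional biological type label.  All analysis modules in
this package operate on this container.  Coordinates are unitless; every
derived length (wiring length, physical path lengths) inherits the input unit.

Node ids are opaque strings.  Internally nodes are densely indexed by load
order; all array-valued attributes (``coords``, ``edges``) follow that order,
which is preserved by I/O round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

NODE_TYPES = ("branch", "endpoint", "inoculum", "penetrating_arteriole", "unknown")


class NetworkValidationError(ValueError):
    """Raised when a network violates the structural invariants."""


@dataclass
class ValidationReport:
    connected: bool
    n_nodes: int
    n_edges: int
    duplicate_coordinate_pairs: int
    messages: list[str] = field(default_factory=list)


@dataclass
class SpatialNetwork:
    """Undirected simple planar-embedded graph with 2D node coordinates.

    Parameters
    ----------
    node_ids:
        Node identifiers in load order (opaque strings).
    coords:
        ``(N, 2)`` float array of node positions, same order as ``node_ids``.
    edges:
        ``(M, 2)`` int array of node *indices*; each row is canonicalised to
        ``i < j`` and the rows are lexicographically sorted, so two networks
        with the same edge set compare equal row-wise.
    node_type:
        Per-node label from :data:`NODE_TYPES`.
    """

    node_ids: list[str]
    coords: np.ndarray
    edges: np.ndarray
    node_type: list[str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise NetworkValidationError("coords must be an (N, 2) array")
        if len(self.node_ids) != len(self.coords):
            raise NetworkValidationError("node_ids and coords length mismatch")
        if self.node_type is None:
            self.node_type = ["unknown"] * self.n_nodes
        self.edges = canonical_edges(self.edges)
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise NetworkValidationError("duplicate node ids")

    # -- basic properties ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_lengths(self) -> np.ndarray:
        if not self.n_edges:
            return np.zeros(0)
        d = self.coords[self.edges[:, 0]] - self.coords[self.edges[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def adjacency(self, weighted: bool = False) -> csr_matrix:
        """Sparse symmetric adjacency; weights are Euclidean edge lengths."""
        n = self.n_nodes
        if not self.n_edges:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.edge_lengths() if weighted else np.ones(self.n_edges)
        return csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        ncomp, _ = connected_components(self.adjacency(), directed=False)
        return ncomp == 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        for i, nid in enumerate(self.node_ids):
            g.add_node(
                nid,
                x=float(self.coords[i, 0]),
                y=float(self.coords[i, 1]),
                type=self.node_type[i],
            )
        for i, j in self.edges:
            g.add_edge(self.node_ids[i], self.node_ids[j])
        return g

    def with_edges(self, edges: np.ndarray, name: str | None = None) -> "SpatialNetwork":
        """New network sharing this one's nodes/coordinates with another edge set."""
        return SpatialNetwork(
            node_ids=list(self.node_ids),
            coords=self.coords.copy(),
            edges=edges,
            node_type=list(self.node_type),
            name=self.name if name is None else name,
        )


def canonical_edges(edges) -> np.ndarray:
    """Canonicalise an edge array: i<j per row, rows lexsorted, duplicates removed."""
    e = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(e) == 0:
        return e
    if (e[:, 0] == e[:, 1]).any():
        raise NetworkValidationError("self-loop edge")
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    return e


def validate(net: SpatialNetwork, require_connected: bool = True) -> ValidationReport:
    """Check the structural invariants; raise on hard violations.

    Duplicate coordinates among distinct nodes are a warning (degenerate
    pairwise distances); zero-length *edges* are an error because every
    spatial measure divides by or sorts on edge length.
    """
    messages: list[str] = []
    if net.n_nodes < 1:
        raise NetworkValidationError("network must have at least one node")
    if not np.isfinite(net.coords).all():
        raise NetworkValidationError("non-finite coordinate")
    if net.n_edges and net.edges.max() >= net.n_nodes:
        raise NetworkValidationError("edge references unknown node index")

    if net.n_edges and (net.edge_lengths() == 0).any():
        raise NetworkValidationError("zero-length edge (coincident endpoints)")

    # duplicate coordinates: warning only
    uniq = np.unique(net.coords, axis=0)
    dup_pairs = net.n_nodes - len(uniq)
    if dup_pairs:
        msg = f"{dup_pairs} duplicated node coordinate(s)"
        messages.append(msg)
        warnings.warn(msg, stacklevel=2)

    connected = net.is_connected()
    if require_connected and not connected:
        raise NetworkValidationError(
            "network is not connected (pass require_connected=False to override)"
        )
    if not connected:
        messages.append("network is not connected")
    return ValidationReport(
        connected=connected,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        duplicate_coordinate_pairs=dup_pairs,
        messages=messages,
    )


def distance_matrix(net: SpatialNetwork) -> np.ndarray:
    """Pairwise Euclidean distance matrix ``D_ij`` (symmetric, zero diagonal)."""
    if np.unique(net.coords, axis=0).shape[0] < net.n_nodes:
        warnings.warn("duplicate coordinates: zero off-diagonal distances", stacklevel=2)
    return squareform(pdist(net.coords)) if net.n_nodes > 1 else np.zeros((1, 1))


def reduce_stubs(net: SpatialNetwork) -> SpatialNetwork:
    """Remove degree-1 penetrating-arteriole nodes and their incident edges.

    Single pass: stubs hanging off the looped backbone are dropped together
    with the surface edge that connects them; nodes that *become* degree 1 are
    not removed (the reduction is not recursive).  Removing degree-1 nodes
    cannot disconnect a connected network; this is asserted after the fact.
    """
    deg = net.degrees()
    types = np.asarray(net.node_type, dtype=object)
    drop = (deg == 1) & (types == "penetrating_arteriole")
    if not drop.any():
        return net
    keep = ~drop
    new_index = -np.ones(net.n_nodes, dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))
    keep_edge = keep[net.edges[:, 0]] & keep[net.edges[:, 1]]
    out = SpatialNetwork(
        node_ids=[nid for nid, k in zip(net.node_ids, keep) if k],
        coords=net.coords[keep],
        edges=new_index[net.edges[keep_edge]],
        node_type=[t for t, k in zip(net.node_type, keep) if k],
        name=net.name,
    )
    assert out.is_connected() or not net.is_connected(), "stub removal disconnected network"
    return out


# -- I/O ----------------------------------------------------------------------

#: coordinates are written with 10 significant digits
_COORD_FMT = "%.10g"


def load_network(
    node_table, edge_table, name: str = "", require_connected: bool = True
) -> SpatialNetwork:
    """Load a network from a node CSV (``id,x,y[,type]``) and edge CSV (``source,target``).

    Edges are deduplicated as unordered pairs.  Unknown node ids, self-loops
    and non-numeric coordinates raise :class:`NetworkValidationError`.
    """
    nodes = pd.read_csv(node_table, dtype={"id": str})
    edges = pd.read_csv(edge_table, dtype=str)
    for col in ("id", "x", "y"):
        if col not in nodes.columns:
            raise NetworkValidationError(f"node table missing column {col!r}")
    for col in ("source", "target"):
        if col not in edges.columns:
            raise NetworkValidationError(f"edge table missing column {col!r}")
    try:
        coords = nodes[["x", "y"]].astype(float).to_numpy()
    except ValueError as exc:
        raise NetworkValidationError(f"non-numeric coordinate: {exc}") from exc
    node_ids = nodes["id"].tolist()
    types = (
        nodes["type"].fillna("unknown").astype(str).tolist()
        if "type" in nodes.columns
        else None
    )
    index = {nid: i for i, nid in enumerate(node_ids)}
    if len(index) != len(node_ids):
        raise NetworkValidationError("duplicate node id in node table")
    try:
        e = np.array(
            [[index[s], index[t]] for s, t in zip(edges["source"], edges["target"])],
            dtype=np.int64,
        ).reshape(-1, 2)
    except KeyError as exc:
        raise NetworkValidationError(f"edge references unknown node id {exc}") from exc
    net = SpatialNetwork(node_ids, coords, e, types, name=name)
    validate(net, require_connected=require_connected)
    return net


def write_network(net: SpatialNetwork, destination, stem: str | None = None) -> tuple[Path, Path]:
    """Write the node/edge CSV pair; returns the two file paths.

    ``load_network`` on the written pair reproduces the network exactly
    (ids, coordinates to 10 significant digits, types, edge set).
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    stem = stem or (net.name or "network")
    node_path = destination / f"{stem}.nodes.csv"
    edge_path = destination / f"{stem}.edges.csv"
    pd.DataFrame(
        {
            "id": net.node_ids,
            "x": [(_COORD_FMT % v) for v in net.coords[:, 0]],
            "y": [(_COORD_FMT % v) for v in net.coords[:, 1]],
            "type": net.node_type,
        }
    ).to_csv(node_path, index=False)
    pd.DataFrame(
        {
            "source": [net.node_ids[i] for i in net.edges[:, 0]],
            "target": [net.node_ids[j] for j in net.edges[:, 1]],
        }
    ).to_csv(edge_path, index=False)
    return node_path, edge_path


def write_graphml(net: SpatialNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def load_graphml(path, name: str = "", require_connected: bool = True) -> SpatialNetwork:
    g = nx.read_graphml(path)
    node_ids = list(g.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    coords = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in node_ids], dtype=float)
    types = [g.nodes[n].get("type", "unknown") for n in node_ids]
    edges = np.array([[index[u], index[v]] for u, v in g.edges], dtype=np.int64).reshape(-1, 2)
    net = SpatialNetwork(node_ids, coords, edges, types, name=name or str(g.name))
    validate(net, require_connected=require_connected)
    return net
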