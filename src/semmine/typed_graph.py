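"""Typed, directed, attributed multigraphs: the target network data model and I/O.

The target network ``G`` is a directed multigraph in which every vertex and
every edge carries a type name drawn from a finite vocabulary (e.g. vertex
types ``Compound``, ``Target``; edge types ``binds_to``, ``similar_to``).
Parallel edges and self-loops are permitted; arbitrary string attributes are
carried as opaque payload, never consulted by the matching algorithm.

Internally a :class:`TypedGraph` wraps a :class:`networkx.MultiDiGraph` whose
edge keys are the unique edge identifiers; the wrapper enforces the typing
invariants and provides the degree / adjacency queries the matcher relies on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "VertexRecord",
    "EdgeRecord",
    "TypedGraph",
    "GraphFormatError",
    "GraphIntegrityError",
    "load_graph",
    "save_graph",
]


class GraphFormatError(ValueError):
    """A serialized graph does not follow the expected dialect."""


class GraphIntegrityError(ValueError):
    """A graph violates a structural invariant (e.g. dangling edge endpoint)."""


@dataclass(frozen=True)
class VertexRecord:
    """A typed vertex: unique id, type name, opaque string attributes."""

    id: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class EdgeRecord:
    """A typed directed edge source -> target; self-loops allowed."""

    id: str
    source: str
    target: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)


class TypedGraph:
    """A typed directed multigraph with attributes.

    Vertices and edges are addressed by unique string identifiers.  Degree
    counts edge multiplicity: parallel edges each count, and a self-loop
    contributes 1 to the in-degree and 1 to the out-degree (hence 2 to the
    total degree).
    """

    def __init__(self, vertices: Iterable[VertexRecord] = (), edges: Iterable[EdgeRecord] = ()):
        self._g = nx.MultiDiGraph()
        self._edge_index: dict[str, tuple[str, str]] = {}
        for v in vertices:
            self.add_vertex(v)
        for e in edges:
            self.add_edge(e)

    # -- construction -----------------------------------------------------

    def add_vertex(self, v: VertexRecord) -> None:
        if not v.id:
            raise GraphIntegrityError("vertex id must be non-empty")
        if v.id in self._g:
            raise GraphIntegrityError(f"duplicate vertex id {v.id!r}")
        self._g.add_node(v.id, type=v.type, attributes=dict(v.attributes))

    def add_edge(self, e: EdgeRecord) -> None:
        if e.id in self._edge_index:
            raise GraphIntegrityError(f"duplicate edge id {e.id!r}")
        for endpoint in (e.source, e.target):
            if endpoint not in self._g:
                raise GraphIntegrityError(
                    f"edge {e.id!r} references unknown vertex {endpoint!r}"
                )
        self._g.add_edge(e.source, e.target, key=e.id, type=e.type,
                         attributes=dict(e.attributes))
        self._edge_index[e.id] = (e.source, e.target)

    def copy(self) -> "TypedGraph":
        out = TypedGraph()
        out._g = self._g.copy()
        out._edge_index = dict(self._edge_index)
        return out

    # -- inspection -------------------------------------------------------

    @property
    def nx(self) -> nx.MultiDiGraph:
        """The underlying networkx multigraph (treat as read-only)."""
        return self._g

    def __contains__(self, vertex_id: str) -> bool:
        return vertex_id in self._g

    def num_vertices(self) -> int:
        return self._g.number_of_nodes()

    def num_edges(self) -> int:
        return self._g.number_of_edges()

    def vertex_ids(self) -> list[str]:
        return list(self._g.nodes)

    def vertex(self, vertex_id: str) -> VertexRecord:
        try:
            data = self._g.nodes[vertex_id]
        except KeyError:
            raise KeyError(f"unknown vertex {vertex_id!r}") from None
        return VertexRecord(vertex_id, data["type"], dict(data["attributes"]))

    def vertex_type(self, vertex_id: str) -> str:
        try:
            return self._g.nodes[vertex_id]["type"]
        except KeyError:
            raise KeyError(f"unknown vertex {vertex_id!r}") from None

    def vertices(self) -> Iterator[VertexRecord]:
        for vid, data in self._g.nodes(data=True):
            yield VertexRecord(vid, data["type"], dict(data["attributes"]))

    def edge(self, edge_id: str) -> EdgeRecord:
        try:
            u, v = self._edge_index[edge_id]
        except KeyError:
            raise KeyError(f"unknown edge {edge_id!r}") from None
        data = self._g.edges[u, v, edge_id]
        return EdgeRecord(edge_id, u, v, data["type"], dict(data["attributes"]))

    def edges(self) -> Iterator[EdgeRecord]:
        for u, v, k, data in self._g.edges(keys=True, data=True):
            yield EdgeRecord(k, u, v, data["type"], dict(data["attributes"]))

    @property
    def vertex_type_vocabulary(self) -> set[str]:
        return {data["type"] for _, data in self._g.nodes(data=True)}

    @property
    def edge_type_vocabulary(self) -> set[str]:
        return {data["type"] for _, _, data in self._g.edges(data=True)}

    def degree(self, vertex_id: str, direction: str = "total") -> int:
        """Multiplicity-counting degree; a self-loop adds 1 in and 1 out."""
        if vertex_id not in self._g:
            raise KeyError(f"unknown vertex {vertex_id!r}")
        if direction == "in":
            return self._g.in_degree(vertex_id)
        if direction == "out":
            return self._g.out_degree(vertex_id)
        if direction == "total":
            return self._g.in_degree(vertex_id) + self._g.out_degree(vertex_id)
        raise ValueError(f"direction must be in/out/total, got {direction!r}")

    def edges_between(self, u: str, v: str) -> list[EdgeRecord]:
        """All edges u->v and v->u (parallel edges included; loops once each)."""
        for x in (u, v):
            if x not in self._g:
                raise KeyError(f"unknown vertex {x!r}")
        out: list[EdgeRecord] = []
        seen: set[str] = set()
        for a, b in ((u, v), (v, u)):
            if self._g.has_edge(a, b):
                for k, data in self._g[a][b].items():
                    if k not in seen:
                        seen.add(k)
                        out.append(EdgeRecord(k, a, b, data["type"], dict(data["attributes"])))
        return out

    def count_edges_directed(self, u: str, v: str) -> int:
        """Number of parallel edges strictly in the direction u -> v."""
        return self._g.number_of_edges(u, v)

    def edge_ids_directed(self, u: str, v: str) -> list[str]:
        if self._g.has_edge(u, v):
            return list(self._g[u][v].keys())
        return []

    def neighbors(self, vertex_id: str) -> set[str]:
        """Undirected neighbor set (successors and predecessors)."""
        return set(self._g.successors(vertex_id)) | set(self._g.predecessors(vertex_id))

    def metagraph(self) -> list[tuple[str, str, str, int]]:
        """Type-level summary: (source type, edge type, target type, count) triples."""
        counts: dict[tuple[str, str, str], int] = {}
        nodes = self._g.nodes
        for u, v, data in self._g.edges(data=True):
            key = (nodes[u]["type"], data["type"], nodes[v]["type"])
            counts[key] = counts.get(key, 0) + 1
        return sorted((s, e, t, c) for (s, e, t), c in counts.items())

    # -- comparisons ------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        mine = {(v.id, v.type, tuple(sorted(v.attributes.items()))) for v in self.vertices()}
        theirs = {(v.id, v.type, tuple(sorted(v.attributes.items()))) for v in other.vertices()}
        if mine != theirs:
            return False
        mine_e = {(e.id, e.source, e.target, e.type, tuple(sorted(e.attributes.items())))
                  for e in self.edges()}
        theirs_e = {(e.id, e.source, e.target, e.type, tuple(sorted(e.attributes.items())))
                    for e in other.edges()}
        return mine_e == theirs_e

    def __repr__(self) -> str:
        return f"TypedGraph(|V|={self.num_vertices()}, |E|={self.num_edges()})"


# -- I/O -------------------------------------------------------------------

_RESERVED_KEYS = {"type", "attributes"}


def _attrs_to_field(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(attrs.items()))


def _field_to_attrs(field_text: str) -> dict[str, str]:
    if not field_text:
        return {}
    out = {}
    for chunk in field_text.split(";"):
        if "=" not in chunk:
            raise GraphFormatError(f"malformed attribute chunk {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def load_graph(path: str | Path, format: str | None = None) -> TypedGraph:
    """Load a typed graph from GraphML or from a TSV node/edge file pair.

    For TSV, ``path`` names the nodes file; the edges file is found by
    replacing ``nodes`` with ``edges`` in the file name (or pass the directory
    containing ``nodes.tsv`` and ``edges.tsv``).
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    if format == "graphml":
        return _load_graphml(path)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _load_graphml(path: Path) -> TypedGraph:
    raw = nx.read_graphml(path, force_multigraph=True)
    g = TypedGraph()
    for node, data in raw.nodes(data=True):
        data = dict(data)
        if "type" not in data:
            raise GraphFormatError(f"node {node!r} lacks the mandatory 'type' data key")
        vtype = data.pop("type")
        g.add_vertex(VertexRecord(str(node), vtype, {k: str(v) for k, v in data.items()}))
    for i, (u, v, k, data) in enumerate(raw.edges(keys=True, data=True)):
        data = dict(data)
        if "type" not in data:
            raise GraphFormatError(f"edge {u!r}->{v!r} lacks the mandatory 'type' data key")
        etype = data.pop("type")
        data.pop("id", None)
        eid = data.pop("edge_id", None) or (k if isinstance(k, str) else f"e{i}")
        g.add_edge(EdgeRecord(str(eid), str(u), str(v), etype,
                              {kk: str(vv) for kk, vv in data.items()}))
    return g


def _tsv_paths(path: Path) -> tuple[Path, Path]:
    if path.is_dir():
        return path / "nodes.tsv", path / "edges.tsv"
    return path, Path(str(path).replace("nodes", "edges"))


def _load_tsv(path: Path) -> TypedGraph:
    nodes_path, edges_path = _tsv_paths(path)
    g = TypedGraph()
    with open(nodes_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row.get("type") in (None, ""):
                raise GraphFormatError(f"node {row.get('id')!r} lacks a type")
            g.add_vertex(VertexRecord(row["id"], row["type"],
                                      _field_to_attrs(row.get("attributes", "") or "")))
    with open(edges_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row.get("type") in (None, ""):
                raise GraphFormatError(f"edge {row.get('id')!r} lacks a type")
            g.add_edge(EdgeRecord(row["id"], row["source"], row["target"], row["type"],
                                  _field_to_attrs(row.get("attributes", "") or "")))
    return g


def save_graph(G: TypedGraph, path: str | Path, format: str | None = None) -> None:
    """Write a typed graph as GraphML or as a TSV node/edge pair (round-trippable)."""
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    if format == "graphml":
        raw = nx.MultiDiGraph()
        for v in G.vertices():
            raw.add_node(v.id, type=v.type, **v.attributes)
        for e in G.edges():
            raw.add_edge(e.source, e.target, key=e.id, type=e.type,
                         edge_id=e.id, **e.attributes)
        nx.write_graphml(raw, path)
    elif format == "tsv":
        nodes_path, edges_path = _tsv_paths(path)
        with open(nodes_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id", "type", "attributes"])
            for v in sorted(G.vertices(), key=lambda r: r.id):
                w.writerow([v.id, v.type, _attrs_to_field(v.attributes)])
        with open(edges_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id", "source", "target", "type", "attributes"])
            for e in sorted(G.edges(), key=lambda r: r.id):
                w.writerow([e.id, e.source, e.target, e.type, _attrs_to_field(e.attributes)])
    else:
        raise ValueError(f"unknown format {format!r}")
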