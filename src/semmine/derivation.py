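"""Deriving query subgraphs from shortest semantic paths.

Given a reference set of drug-target pairs known from newer knowledge but not
yet linked in the network, the typed shortest path between each pair (in the
undirected view of the network) is turned into a query: one role per path
vertex carrying its type, one edge per path edge carrying its type and stored
direction, and an inference annotation between the endpoint roles.  Queries
that are isomorphic as typed digraphs (including the inference annotation)
are collapsed to one canonical representative with a multiplicity.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .matcher import QueryEdge, QueryGraph
from .typed_graph import EdgeRecord, TypedGraph, VertexRecord

__all__ = [
    "ReferenceInteractionSet",
    "NoPathError",
    "load_reference_pairs",
    "relevant_interactions",
    "shortest_semantic_path",
    "path_to_query",
    "dedup_queries",
    "derive_queries",
]


class NoPathError(ValueError):
    """The two vertices lie in different components of the network."""


@dataclass
class ReferenceInteractionSet:
    """A labelled set of known drug-target pairs used for scoring."""

    pairs: set[tuple[str, str]]
    label: str = "reference"


def load_reference_pairs(path: str | Path, label: str | None = None) -> ReferenceInteractionSet:
    """Read a two-column (drug_id, target_id) TSV, with or without a header."""
    pairs = set()
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] in ("drug_id", "drug"):
                continue
            pairs.add((row[0], row[1]))
    return ReferenceInteractionSet(pairs, label or Path(path).stem)


def relevant_interactions(
    G: TypedGraph,
    candidate_pairs,
    interaction_edge_type: str = "binds_to",
    label: str = "relevant",
) -> ReferenceInteractionSet:
    """Keep candidate pairs whose drug and target both exist in G but whose
    interaction edge (in either direction) is absent."""
    kept = set()
    for drug, target in candidate_pairs:
        if drug not in G or target not in G:
            continue
        linked = any(e.type == interaction_edge_type
                     for e in G.edges_between(drug, target))
        if not linked:
            kept.add((drug, target))
    return ReferenceInteractionSet(kept, label)


def shortest_semantic_path(
    G: TypedGraph, a: str, b: str
) -> tuple[list[VertexRecord], list[EdgeRecord]]:
    """Minimum-hop path a..b in the undirected view, deterministic among ties.

    Among equal-length paths the lexicographically smallest vertex-id sequence
    is chosen; for parallel edges between consecutive path vertices the edge
    with the smallest id is reported, with its stored direction and type.
    """
    for x in (a, b):
        if x not in G:
            raise KeyError(f"unknown vertex {x!r}")
    und = nx.Graph(G.nx)
    try:
        dist = nx.single_source_shortest_path_length(und, b)
    except nx.NodeNotFound:  # pragma: no cover
        raise NoPathError(f"no path between {a!r} and {b!r}")
    if a not in dist:
        raise NoPathError(f"no path between {a!r} and {b!r}")
    path = [a]
    node = a
    while node != b:
        node = min(n for n in und.neighbors(node) if dist.get(n, -1) == dist[node] - 1)
        path.append(node)
    vertices = [G.vertex(v) for v in path]
    edges = []
    for u, v in zip(path, path[1:]):
        edges.append(min(G.edges_between(u, v), key=lambda e: e.id))
    return vertices, edges


def path_to_query(
    path: tuple[list[VertexRecord], list[EdgeRecord]],
    inferred_edge_type: str = "binds_to",
    name: str | None = None,
) -> QueryGraph:
    """Turn a typed path into a type-level query with an inference annotation.

    Each path vertex becomes a distinct role carrying its type (identities are
    not pinned); the inference runs from the first role (the drug) to the last
    (the target)."""
    vertices, edges = path
    if len(edges) == 0:
        raise ValueError("cannot derive a query from a zero-length path")
    role_of = {v.id: f"r{i}" for i, v in enumerate(vertices)}
    roles = {role_of[v.id]: v.type for v in vertices}
    qedges = [QueryEdge(f"qe{i}", role_of[e.source], role_of[e.target], e.type)
              for i, e in enumerate(edges)]
    inference = (role_of[vertices[0].id], role_of[vertices[-1].id], inferred_edge_type)
    return QueryGraph(roles, qedges, inference, name=name)


def _canonical_form(Q: QueryGraph) -> tuple:
    """Canonical label under type-respecting role permutations.

    Roles of equal type are interchangeable candidates; all consistent
    permutations are enumerated (queries are capped at 9 roles so the
    type-partitioned factorial stays small) and the minimum serialized form
    is the class representative."""
    roles = sorted(Q.roles)
    by_type: dict[str, list[str]] = {}
    for r in roles:
        by_type.setdefault(Q.roles[r], []).append(r)
    types = sorted(by_type)
    slots: list[str] = [r for t in types for r in by_type[t]]

    best = None
    group_perms = [itertools.permutations(by_type[t]) for t in types]
    for combo in itertools.product(*group_perms):
        perm_roles = [r for group in combo for r in group]
        relabel = {orig: f"n{i}" for i, orig in zip(range(len(slots)), perm_roles)}
        vseq = tuple(sorted((relabel[r], Q.roles[r]) for r in roles))
        eseq = tuple(sorted((relabel[e.source], relabel[e.target], e.type)
                            for e in Q.edges))
        inf = None
        if Q.inference:
            inf = (relabel[Q.inference[0]], relabel[Q.inference[1]], Q.inference[2])
        form = (vseq, eseq, inf)
        if best is None or form < best:
            best = form
    return best


def dedup_queries(
    queries, max_vertices: int = 9
) -> list[tuple[QueryGraph, int]]:
    """Group queries by typed-digraph isomorphism (inference included); one
    representative per class with its multiplicity.  Queries larger than
    ``max_vertices`` are discarded with a warning."""
    classes: dict[tuple, tuple[QueryGraph, int]] = {}
    for Q in queries:
        if Q.num_vertices() > max_vertices:
            warnings.warn(f"discarding query {Q.name or ''} with "
                          f"{Q.num_vertices()} > {max_vertices} roles", stacklevel=2)
            continue
        form = _canonical_form(Q)
        if form in classes:
            rep, count = classes[form]
            classes[form] = (rep, count + 1)
        else:
            classes[form] = (Q, 1)
    return list(classes.values())


def derive_queries(
    G: TypedGraph,
    reference: ReferenceInteractionSet,
    inferred_edge_type: str = "binds_to",
    max_vertices: int = 9,
) -> tuple[list[tuple[QueryGraph, int]], list[tuple[str, str]]]:
    """Full derivation pipeline: shortest paths for every reference pair,
    conversion to queries, deduplication.  Returns (classes, skipped pairs)."""
    queries, skipped = [], []
    for i, (drug, target) in enumerate(sorted(reference.pairs)):
        try:
            path = shortest_semantic_path(G, drug, target)
        except (NoPathError, KeyError):
            skipped.append((drug, target))
            continue
        if not path[1]:
            skipped.append((drug, target))
            continue
        queries.append(path_to_query(path, inferred_edge_type, name=f"derived{i}"))
    return dedup_queries(queries, max_vertices), skipped
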