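"""Synthetic data generators used to characterise the search.

Random target networks replicate the type-level structure of a real
integrated network: exact per-type vertex counts and, for every
(source type, edge type, target type) triple of the metagraph, an exact
number of edges whose endpoints are sampled uniformly from the type
populations (self-loops resampled, parallel edges allowed).  This preserves
the per-type average in- and out-degrees by construction.

Planted query instances are added as vertex-disjoint fresh components, so a
rigid query (one with no non-trivial type-respecting automorphism) planted k
times raises the mapping count by exactly k -- the spiked-vs-unspiked
arithmetic used to verify search accuracy.

``chlorpromazine_fixture`` builds the classic guilt-by-association example:
a drug structurally similar to another drug with a known target, from which
a binding of the first drug to that target is inferred.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matcher import QueryEdge, QueryGraph
from .typed_graph import EdgeRecord, TypedGraph, VertexRecord

__all__ = [
    "SyntheticSpec",
    "spec_from_graph",
    "random_graph",
    "random_query",
    "plant_instances",
    "chlorpromazine_fixture",
    "load_spec",
    "save_spec",
]


@dataclass
class SyntheticSpec:
    """Type-level recipe for a random target network."""

    vertex_counts: dict[str, int]
    triple_rates: dict[tuple[str, str, str], int]
    seed: int = 0

    def __post_init__(self):
        for t, c in self.vertex_counts.items():
            if c < 0:
                raise ValueError(f"negative vertex count for type {t!r}")
        for (s, _, t), c in self.triple_rates.items():
            if c < 0:
                raise ValueError("negative edge count in triple rates")
            for ty in (s, t):
                if ty not in self.vertex_counts:
                    raise ValueError(f"triple references undeclared vertex type {ty!r}")


def load_spec(path: str | Path) -> SyntheticSpec:
    with open(path) as fh:
        doc = json.load(fh)
    triples = {(t["source"], t["edge"], t["target"]): int(t["count"])
               for t in doc["triples"]}
    return SyntheticSpec(dict(doc["vertex_counts"]), triples, int(doc.get("seed", 0)))


def save_spec(spec: SyntheticSpec, path: str | Path) -> None:
    doc = {
        "vertex_counts": spec.vertex_counts,
        "triples": [{"source": s, "edge": e, "target": t, "count": c}
                    for (s, e, t), c in sorted(spec.triple_rates.items())],
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def spec_from_graph(G: TypedGraph) -> SyntheticSpec:
    """Read the per-type vertex counts and metagraph edge counts off a graph."""
    counts: dict[str, int] = {}
    for v in G.vertices():
        counts[v.type] = counts.get(v.type, 0) + 1
    triples = {(s, e, t): c for s, e, t, c in G.metagraph()}
    return SyntheticSpec(counts, triples)


def random_graph(spec: SyntheticSpec, seed: int | None = None) -> TypedGraph:
    """Random typed multigraph with exact per-type vertex and per-triple edge
    counts; endpoints uniform over the type populations, self-loops
    resampled, parallel edges allowed.  Reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g = TypedGraph()
    pops: dict[str, list[str]] = {}
    for vtype in sorted(spec.vertex_counts):
        ids = [f"{vtype}_{i}" for i in range(spec.vertex_counts[vtype])]
        pops[vtype] = ids
        for vid in ids:
            g.add_vertex(VertexRecord(vid, vtype))
    eid = 0
    for (stype, etype, ttype) in sorted(spec.triple_rates):
        count = spec.triple_rates[(stype, etype, ttype)]
        src_pop, dst_pop = pops[stype], pops[ttype]
        if count > 0 and (not src_pop or not dst_pop):
            raise ValueError(f"triple ({stype},{etype},{ttype}) references an "
                             "empty type population")
        if count > 0 and stype == ttype and len(src_pop) < 2:
            raise ValueError(f"cannot avoid self-loops for triple ({stype},{etype},{ttype})")
        for _ in range(count):
            while True:
                u = src_pop[int(rng.integers(len(src_pop)))]
                v = dst_pop[int(rng.integers(len(dst_pop)))]
                if u != v:
                    break
            g.add_edge(EdgeRecord(f"e{eid}", u, v, etype))
            eid += 1
    return g


def random_query(
    n_vertices: int,
    vertex_types,
    edge_types,
    extra_edges: int = 0,
    seed: int = 0,
    inference: bool = False,
) -> QueryGraph:
    """Random connected query: a random spanning tree plus ``extra_edges``
    additional edges between not-yet-adjacent role pairs (so a query with
    pairwise distinct vertex types is rigid and free of parallel edges).

    When ``vertex_types`` has exactly ``n_vertices`` entries they are
    assigned positionally; otherwise types are drawn at random.
    """
    if not 2 <= n_vertices:
        raise ValueError("a query needs at least 2 roles")
    rng = np.random.default_rng(seed)
    vertex_types = list(vertex_types)
    edge_types = list(edge_types)
    roles = [f"v{i}" for i in range(n_vertices)]
    if len(vertex_types) == n_vertices:
        types = dict(zip(roles, vertex_types))
    else:
        types = {r: vertex_types[int(rng.integers(len(vertex_types)))] for r in roles}

    max_extra = n_vertices * (n_vertices - 1) // 2 - (n_vertices - 1)
    if extra_edges < 0 or extra_edges > max_extra:
        raise ValueError(f"extra_edges must lie in [0, {max_extra}] for "
                         f"{n_vertices} roles")

    edges: list[QueryEdge] = []
    adjacent: set[frozenset] = set()
    for i in range(1, n_vertices):
        j = int(rng.integers(i))
        a, b = roles[i], roles[j]
        if rng.integers(2):
            a, b = b, a
        edges.append(QueryEdge(f"qe{len(edges)}", a, b,
                               edge_types[int(rng.integers(len(edge_types)))]))
        adjacent.add(frozenset((a, b)))
    candidates = [frozenset((a, b)) for a, b in itertools.combinations(roles, 2)
                  if frozenset((a, b)) not in adjacent]
    picks = rng.choice(len(candidates), size=extra_edges, replace=False) \
        if extra_edges else []
    for idx in picks:
        a, b = sorted(candidates[int(idx)])
        if rng.integers(2):
            a, b = b, a
        edges.append(QueryEdge(f"qe{len(edges)}", a, b,
                               edge_types[int(rng.integers(len(edge_types)))]))

    inf = (roles[0], roles[-1], edge_types[0]) if inference else None
    return QueryGraph(types, edges, inf, name=f"rand{seed}")


def plant_instances(G: TypedGraph, Q: QueryGraph, k: int, seed: int = 0) -> TypedGraph:
    """Add k vertex-disjoint fresh-vertex copies of Q as isolated components.

    Each copy carries exactly Q's edges and no edge to pre-existing vertices,
    so for a rigid query the search finds exactly k additional mappings."""
    out = G.copy()
    for i in range(k):
        name_of = {r: f"plant{seed}_{i}_{r}" for r in Q.roles}
        for r, t in sorted(Q.roles.items()):
            out.add_vertex(VertexRecord(name_of[r], t))
        for j, e in enumerate(Q.edges):
            out.add_edge(EdgeRecord(f"plantE{seed}_{i}_{j}", name_of[e.source],
                                    name_of[e.target], e.type))
    return out


def chlorpromazine_fixture() -> tuple[TypedGraph, QueryGraph]:
    """The guilt-by-association worked example.

    Chlorpromazine binds three annotated targets, none explaining its
    antihistaminic effect; it is structurally similar to trimeprazine, which
    binds the Histamine H1 receptor.  The triad query (compound similar to a
    compound that binds a target) infers chlorpromazine - H1 receptor.
    """
    g = TypedGraph()
    for vid in ("chlorpromazine", "trimeprazine"):
        g.add_vertex(VertexRecord(vid, "Compound"))
    for vid in ("T1", "T2", "T3", "Histamine H1 receptor"):
        g.add_vertex(VertexRecord(vid, "Target"))
    for i, t in enumerate(("T1", "T2", "T3"), start=1):
        g.add_edge(EdgeRecord(f"b{i}", "chlorpromazine", t, "binds_to"))
    g.add_edge(EdgeRecord("s1", "chlorpromazine", "trimeprazine", "similar_to"))
    g.add_edge(EdgeRecord("b4", "trimeprazine", "Histamine H1 receptor", "binds_to"))

    query = QueryGraph(
        {"C1": "Compound", "C2": "Compound", "T": "Target"},
        [QueryEdge("q_sim", "C1", "C2", "similar_to"),
         QueryEdge("q_bind", "C2", "T", "binds_to")],
        inference=("C1", "T", "binds_to"),
        name="similar-compound-binds",
    )
    return g, query
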