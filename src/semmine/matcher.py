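"""Exhaustive semantic subgraph matching.

A query (semantic subgraph) is a small connected typed directed multigraph
whose roles stand for the kinds of entity sought (e.g. two compounds and a
target).  A mapping embeds the query into the target network: an injective
assignment of query roles to target vertices and of query edges to distinct
target edges that preserves direction, passes the semantic threshold, and --
under the closed-world assumption -- leaves no target edge between mapped
vertices without a query counterpart (the match is induced).

The search is a VF-style depth-first backtracking over an initial candidate
set restricted by vertex type and degree, extending along neighbors of the
already-mapped region, with the closed-world edge-count equality enforced
incrementally.  ``brute_force_search`` is a deliberately independent oracle
that enumerates injective assignments outright and post-filters them; it
shares no candidate machinery with ``search`` and is used to validate it.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .semantics import SDCMatrices, SearchConfig, _EPS
from .typed_graph import TypedGraph

__all__ = [
    "QueryGraph",
    "QueryEdge",
    "Mapping",
    "load_query",
    "save_query",
    "select_anchor",
    "initial_candidates",
    "search",
    "brute_force_search",
    "mappings_to_inferences",
    "write_mappings_jsonl",
]


@dataclass(frozen=True)
class QueryEdge:
    id: str
    source: str
    target: str
    type: str


class QueryGraph:
    """A semantic query: typed roles, typed directed edges, optional inference.

    The inference annotation names the (drug role, target role) pair between
    which an edge of the given type is inferred for every mapping found; the
    inferred edge type need not occur among the structural edges.
    """

    def __init__(
        self,
        vertices: dict[str, str] | Iterable[tuple[str, str]],
        edges: Iterable[tuple[str, str, str] | tuple[str, str, str, str] | QueryEdge],
        inference: tuple[str, str, str] | None = None,
        name: str | None = None,
    ):
        self.roles: dict[str, str] = dict(vertices)
        if len(self.roles) < 2:
            raise ValueError("a query needs at least 2 roles")
        self.edges: list[QueryEdge] = []
        for i, e in enumerate(edges):
            if isinstance(e, QueryEdge):
                qe = e
            elif len(e) == 4:
                qe = QueryEdge(*e)
            else:
                qe = QueryEdge(f"qe{i}", *e)
            for endpoint in (qe.source, qe.target):
                if endpoint not in self.roles:
                    raise ValueError(f"query edge {qe.id!r} references unknown role {endpoint!r}")
            self.edges.append(qe)
        if len({e.id for e in self.edges}) != len(self.edges):
            raise ValueError("query edge ids must be unique")
        self.inference = tuple(inference) if inference else None
        if self.inference:
            for role in self.inference[:2]:
                if role not in self.roles:
                    raise ValueError(f"inference references unknown role {role!r}")
        self.name = name
        self._adj: dict[str, set[str]] = {r: set() for r in self.roles}
        self._dir_counts: dict[tuple[str, str], int] = {}
        for e in self.edges:
            self._adj[e.source].add(e.target)
            self._adj[e.target].add(e.source)
            self._dir_counts[(e.source, e.target)] = self._dir_counts.get((e.source, e.target), 0) + 1
        if not self.is_connected():
            raise ValueError("query must be connected in the undirected view")

    # -- structure ---------------------------------------------------------

    def num_vertices(self) -> int:
        return len(self.roles)

    def num_edges(self) -> int:
        return len(self.edges)

    def role_type(self, role: str) -> str:
        return self.roles[role]

    def edge_type(self, edge_id: str) -> str:
        for e in self.edges:
            if e.id == edge_id:
                return e.type
        raise KeyError(edge_id)

    def degree(self, role: str) -> int:
        """Total degree counting multiplicity; self-loops count twice."""
        d = 0
        for e in self.edges:
            if e.source == role:
                d += 1
            if e.target == role:
                d += 1
        return d

    def undirected_neighbors(self, role: str) -> set[str]:
        return set(self._adj[role])

    def count_edges_directed(self, src: str, dst: str) -> int:
        return self._dir_counts.get((src, dst), 0)

    def is_connected(self) -> bool:
        roles = list(self.roles)
        seen = {roles[0]}
        stack = [roles[0]]
        while stack:
            r = stack.pop()
            for s in self._adj[r]:
                if s not in seen:
                    seen.add(s)
                    stack.append(s)
        return len(seen) == len(self.roles)

    def relabeled(self, rename: dict[str, str]) -> "QueryGraph":
        return QueryGraph(
            {rename[r]: t for r, t in self.roles.items()},
            [QueryEdge(e.id, rename[e.source], rename[e.target], e.type) for e in self.edges],
            (rename[self.inference[0]], rename[self.inference[1]], self.inference[2])
            if self.inference else None,
            name=self.name,
        )

    def __repr__(self) -> str:
        return (f"QueryGraph({self.name or 'unnamed'}, |V|={self.num_vertices()}, "
                f"|E|={self.num_edges()})")


@dataclass
class Mapping:
    """An embedding of a query into the target graph, with its semantic score."""

    vertex_assignment: dict[str, str]
    edge_assignment: dict[str, str]
    ss: float = 1.0

    def key(self) -> tuple:
        """Identity of the mapping: vertex plus edge assignment."""
        return (tuple(sorted(self.vertex_assignment.items())),
                tuple(sorted(self.edge_assignment.items())))

    def __eq__(self, other):
        return isinstance(other, Mapping) and self.key() == other.key()

    def __hash__(self):
        return hash(self.key())


# -- query JSON I/O --------------------------------------------------------


def load_query(path: str | Path) -> QueryGraph:
    with open(path) as fh:
        doc = json.load(fh)
    vertices = {v["role"]: v["type"] for v in doc["vertices"]}
    edges = []
    for i, e in enumerate(doc["edges"]):
        edges.append(QueryEdge(e.get("id", f"qe{i}"), e["source"], e["target"], e["type"]))
    inference = None
    if doc.get("inference"):
        inf = doc["inference"]
        inference = (inf["source"], inf["target"], inf["type"])
    return QueryGraph(vertices, edges, inference, name=doc.get("name") or Path(path).stem)


def save_query(Q: QueryGraph, path: str | Path) -> None:
    doc = {
        "name": Q.name,
        "vertices": [{"role": r, "type": t} for r, t in sorted(Q.roles.items())],
        "edges": [{"id": e.id, "source": e.source, "target": e.target, "type": e.type}
                  for e in Q.edges],
    }
    if Q.inference:
        doc["inference"] = {"source": Q.inference[0], "target": Q.inference[1],
                            "type": Q.inference[2]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# -- anchor and candidates -------------------------------------------------


def select_anchor(Q: QueryGraph, anchor_type: str) -> str:
    """The query role the search starts from.

    Among roles of the anchor type, the one of maximum degree (ties broken by
    smallest role id).  If the query has no role of that type, the globally
    maximum-degree role is used instead and a warning is issued.
    """
    typed = [r for r, t in Q.roles.items() if t == anchor_type]
    pool = typed
    if not pool:
        warnings.warn(
            f"query {Q.name or ''} has no vertex of anchor type {anchor_type!r}; "
            "falling back to the maximum-degree vertex", stacklevel=2)
        pool = list(Q.roles)
    return min(pool, key=lambda r: (-Q.degree(r), r))


def initial_candidates(
    G: TypedGraph, Q: QueryGraph, anchor: str, matrices: SDCMatrices, cfg: SearchConfig
) -> list[str]:
    """Target vertices eligible to match the anchor role."""
    n_elem = Q.num_vertices() + Q.num_edges()
    return [v for v in G.vertex_ids()
            if _vertex_admissible(G, Q, anchor, v, matrices, cfg, n_elem)]


def _vertex_admissible(G, Q, role, vid, matrices, cfg, n_elements,
                       partial_sum: float = 0.0, assigned_elements: int = 0) -> bool:
    s = matrices.score_vertex(Q.role_type(role), G.vertex_type(vid))
    if cfg.mode == "per_element":
        if s < cfg.st - _EPS:
            return False
    else:
        # admissible bound: even if all remaining elements score 1 the mean
        # cannot reach st => prune
        best = partial_sum + s + (n_elements - assigned_elements - 1)
        if best < cfg.st * n_elements - _EPS:
            return False
    dg = G.degree(vid, "total")
    dq = Q.degree(role)
    if cfg.strict_degree:
        return dg == dq
    return dg >= dq


def _edge_assignment_combos(
    G: TypedGraph,
    Q: QueryGraph,
    matrices: SDCMatrices,
    st: float,
    per_element_check: bool,
    assignment: dict[str, str],
) -> list[tuple[dict[str, str], float]]:
    """All injective assignments of query edges to target edges for a complete
    vertex assignment, as (edge_assignment, edge score sum) pairs.

    Parallel query edges between the same role pair are assigned to distinct
    parallel target edges; with ``per_element_check`` every edge score must
    reach the threshold."""
    by_pair: dict[tuple[str, str], list[QueryEdge]] = {}
    for e in Q.edges:
        by_pair.setdefault((e.source, e.target), []).append(e)
    group_opts = []
    for (s, t), qedges in by_pair.items():
        gedges = G.edge_ids_directed(assignment[s], assignment[t])
        if len(gedges) < len(qedges):
            return []
        opts = []
        for perm in itertools.permutations(gedges, len(qedges)):
            scores = []
            ok = True
            for qe, ge in zip(qedges, perm):
                sc = matrices.score_edge(qe.type, G.edge(ge).type)
                if per_element_check and sc < st - _EPS:
                    ok = False
                    break
                scores.append(sc)
            if ok:
                opts.append((tuple((qe.id, ge) for qe, ge in zip(qedges, perm)),
                             sum(scores)))
        if not opts:
            return []
        group_opts.append(opts)
    out = []
    for combo in itertools.product(*group_opts):
        out.append((dict(kv for opt, _ in combo for kv in opt),
                    sum(s for _, s in combo)))
    return out


def induced_assignment_ok(G: TypedGraph, Q: QueryGraph, assignment: dict[str, str]) -> bool:
    """Closed-world check: between every ordered pair of mapped vertices (and
    on self-loops) the target edge count equals the query edge count."""
    roles = list(Q.roles)
    for i, r in enumerate(roles):
        for s in roles[i:]:
            pairs = ((r, s), (s, r)) if r != s else ((r, r),)
            for a, b in pairs:
                if G.count_edges_directed(assignment[a], assignment[b]) != \
                        Q.count_edges_directed(a, b):
                    return False
    return True


# -- the backtracking search ----------------------------------------------


def search(
    G: TypedGraph,
    Q: QueryGraph,
    matrices: SDCMatrices,
    cfg: SearchConfig | None = None,
) -> list[Mapping]:
    """All mappings of Q in G meeting the closed-world and semantic contracts.

    Exhaustive up to ``cfg.max_mappings``.  Expects G to have been pruned
    already if ``cfg.prune_enabled`` (see :func:`semmine.pipeline.mine_query`
    for the orchestrated run).
    """
    cfg = cfg or SearchConfig()
    return _search_impl(G, Q, matrices, cfg)


def _search_impl(
    G: TypedGraph,
    Q: QueryGraph,
    matrices: SDCMatrices,
    cfg: SearchConfig,
    *,
    induced: bool = True,
    role_min_degree: dict[str, int] | None = None,
    role_domains: dict[str, set[str]] | None = None,
    total_elements: int | None = None,
    check_threshold: bool = True,
    anchor_role: str | None = None,
) -> list[Mapping]:
    """Backtracking engine; the keyword knobs exist for the split-and-join
    strategy, which searches query parts non-induced and re-checks the joined
    mapping (public callers never pass them)."""
    n_elem = total_elements if total_elements is not None else Q.num_vertices() + Q.num_edges()
    anchor = anchor_role if anchor_role is not None else select_anchor(Q, cfg.anchor_type)
    role_min_degree = role_min_degree or {}
    role_domains = role_domains or {}

    roots = []
    for v in sorted(G.vertex_ids()):
        if anchor in role_domains and v not in role_domains[anchor]:
            continue
        if not _vertex_admissible(G, Q, anchor, v, matrices, cfg, n_elem):
            continue
        if G.degree(v, "total") < role_min_degree.get(anchor, 0):
            continue
        roots.append(v)

    results: list[Mapping] = []
    seen_orbits: set = set()
    role_order_cache = list(Q.roles)

    def pair_counts_ok(assignment: dict[str, str], role: str, vid: str) -> bool:
        # self-loops
        req_loop = Q.count_edges_directed(role, role)
        have_loop = G.count_edges_directed(vid, vid)
        if induced:
            if have_loop != req_loop:
                return False
        elif have_loop < req_loop:
            return False
        for s, u in assignment.items():
            req_out = Q.count_edges_directed(s, role)
            req_in = Q.count_edges_directed(role, s)
            have_out = G.count_edges_directed(u, vid)
            have_in = G.count_edges_directed(vid, u)
            if induced:
                if have_out != req_out or have_in != req_in:
                    return False
            else:
                if have_out < req_out or have_in < req_in:
                    return False
        return True

    def next_role(assigned: dict[str, str]) -> str | None:
        best = None
        for r in role_order_cache:
            if r in assigned:
                continue
            if not (Q.undirected_neighbors(r) & assigned.keys()):
                continue
            if best is None or (-Q.degree(r), r) < (-Q.degree(best), best):
                best = r
        return best

    def finish(assignment: dict[str, str], vscore_sum: float) -> bool:
        """Enumerate edge assignments for a complete vertex assignment.
        Returns False when the mapping cap has been reached."""
        per_elem_check = cfg.mode == "per_element" and check_threshold
        combos = _edge_assignment_combos(G, Q, matrices, cfg.st, per_elem_check, assignment)
        for edge_assignment, escore_sum in combos:
            total = vscore_sum + escore_sum
            own_n = Q.num_vertices() + Q.num_edges()
            if check_threshold and cfg.mode == "cumulative":
                if total_elements is None:
                    if total / own_n < cfg.st - _EPS:
                        continue
                else:
                    # part search: keep iff the full mapping could still pass
                    if total + (n_elem - own_n) < cfg.st * n_elem - _EPS:
                        continue
            m = Mapping(dict(assignment), edge_assignment, total / own_n)
            if cfg.dedup_orbits:
                orbit = (frozenset(assignment.values()),
                         frozenset(edge_assignment.values()))
                if orbit in seen_orbits:
                    continue
                seen_orbits.add(orbit)
            results.append(m)
            if cfg.max_mappings is not None and len(results) >= cfg.max_mappings:
                return False
        return True

    def extend(assignment: dict[str, str], used: set[str], vscore_sum: float) -> bool:
        if len(assignment) == Q.num_vertices():
            return finish(assignment, vscore_sum)
        role = next_role(assignment)
        if role is None:  # unreachable for connected queries
            return True
        # candidates drawn from neighbors of an already-mapped neighbor role
        ref = min(Q.undirected_neighbors(role) & assignment.keys())
        candidates = sorted(G.neighbors(assignment[ref]))
        dom = role_domains.get(role)
        for v in candidates:
            if v in used:
                continue
            if dom is not None and v not in dom:
                continue
            if not _vertex_admissible(G, Q, role, v, matrices, cfg, n_elem,
                                      vscore_sum, len(assignment)):
                continue
            if G.degree(v, "total") < role_min_degree.get(role, 0):
                continue
            if not pair_counts_ok(assignment, role, v):
                continue
            s = matrices.score_vertex(Q.role_type(role), G.vertex_type(v))
            assignment[role] = v
            used.add(v)
            keep_going = extend(assignment, used, vscore_sum + s)
            del assignment[role]
            used.discard(v)
            if not keep_going:
                return False
        return True

    for root in roots:
        if not pair_counts_ok({}, anchor, root):
            continue
        s = matrices.score_vertex(Q.role_type(anchor), G.vertex_type(root))
        if not extend({anchor: root}, {root}, s):
            break
    return results


# -- brute-force oracle ----------------------------------------------------


class OracleSizeError(ValueError):
    """The target graph is too large for exhaustive enumeration."""


def brute_force_search(
    G: TypedGraph,
    Q: QueryGraph,
    matrices: SDCMatrices,
    cfg: SearchConfig | None = None,
    guard: int = 60,
) -> list[Mapping]:
    """Reference oracle: enumerate injective role assignments and post-filter.

    Independent of :func:`search`: no anchor selection, no candidate sets, no
    incremental closed-world bookkeeping.  Roles are enumerated in a fixed
    breadth-first order over all target vertices; a prefix is abandoned only
    when a query edge among already-assigned roles has no counterpart, which
    leaves the accepted set identical to unpruned enumeration.
    """
    cfg = cfg or SearchConfig()
    if G.num_vertices() > guard:
        raise OracleSizeError(
            f"brute-force oracle limited to {guard} vertices, got {G.num_vertices()}")
    if Q.num_vertices() > G.num_vertices():
        return []

    # breadth-first role order from the smallest role id
    order: list[str] = []
    start = min(Q.roles)
    queue = [start]
    seen = {start}
    while queue:
        r = queue.pop(0)
        order.append(r)
        for s in sorted(Q.undirected_neighbors(r)):
            if s not in seen:
                seen.add(s)
                queue.append(s)

    vertices = sorted(G.vertex_ids())
    results: list[Mapping] = []

    def prefix_ok(assignment: dict[str, str]) -> bool:
        for (s, t), req in Q._dir_counts.items():
            if s in assignment and t in assignment:
                if G.count_edges_directed(assignment[s], assignment[t]) < req:
                    return False
        return True

    def full_check(assignment: dict[str, str]) -> None:
        # closed world: edge counts between every ordered pair of mapped
        # vertices (and loops) must equal the query's counts exactly
        roles = list(Q.roles)
        for i, r in enumerate(roles):
            for s in roles[i:]:
                for a, b in ((r, s), (s, r)) if r != s else ((r, r),):
                    if G.count_edges_directed(assignment[a], assignment[b]) != \
                            Q.count_edges_directed(a, b):
                        return
        if cfg.strict_degree:
            for r, v in assignment.items():
                if G.degree(v, "total") != Q.degree(r):
                    return
        # vertex scores
        vscores = [matrices.score_vertex(Q.role_type(r), G.vertex_type(v))
                   for r, v in assignment.items()]
        if cfg.mode == "per_element" and any(s < cfg.st - _EPS for s in vscores):
            return
        # enumerate edge assignments per ordered role pair
        by_pair: dict[tuple[str, str], list[QueryEdge]] = {}
        for e in Q.edges:
            by_pair.setdefault((e.source, e.target), []).append(e)
        group_opts = []
        for (s, t), qedges in by_pair.items():
            gedges = G.edge_ids_directed(assignment[s], assignment[t])
            opts = []
            for perm in itertools.permutations(gedges, len(qedges)):
                scores = [matrices.score_edge(qe.type, G.edge(ge).type)
                          for qe, ge in zip(qedges, perm)]
                if cfg.mode == "per_element" and any(x < cfg.st - _EPS for x in scores):
                    continue
                opts.append((tuple((qe.id, ge) for qe, ge in zip(qedges, perm)),
                             sum(scores)))
            if not opts:
                return
            group_opts.append(opts)
        n_elem = Q.num_vertices() + Q.num_edges()
        for combo in itertools.product(*group_opts):
            total = sum(vscores) + sum(s for _, s in combo)
            ss = total / n_elem
            if cfg.mode == "cumulative" and ss < cfg.st - _EPS:
                continue
            m = Mapping(dict(assignment), dict(kv for opt, _ in combo for kv in opt), ss)
            results.append(m)

    def recurse(idx: int, assignment: dict[str, str], used: set[str]) -> None:
        if idx == len(order):
            full_check(assignment)
            return
        role = order[idx]
        for v in vertices:
            if v in used:
                continue
            assignment[role] = v
            if prefix_ok(assignment):
                used.add(v)
                recurse(idx + 1, assignment, used)
                used.discard(v)
            del assignment[role]

    recurse(0, {}, set())
    if cfg.dedup_orbits:
        kept, seen_orbits = [], set()
        for m in results:
            orbit = (frozenset(m.vertex_assignment.values()),
                     frozenset(m.edge_assignment.values()))
            if orbit not in seen_orbits:
                seen_orbits.add(orbit)
                kept.append(m)
        results = kept
    if cfg.max_mappings is not None:
        results = results[:cfg.max_mappings]
    return results


# -- inference extraction --------------------------------------------------


def mappings_to_inferences(
    mappings: Sequence[Mapping], Q: QueryGraph
) -> list[tuple[str, str]]:
    """Read off the (drug, target) vertex pair of each mapping.

    Duplicates are preserved; deduplication happens in ranking.
    """
    if not Q.inference:
        raise ValueError("query has no inference annotation")
    src, dst, _ = Q.inference
    return [(m.vertex_assignment[src], m.vertex_assignment[dst]) for m in mappings]


def write_mappings_jsonl(mappings: Sequence[Mapping], Q: QueryGraph,
                         path: str | Path) -> None:
    with open(path, "a") as fh:
        for m in mappings:
            fh.write(json.dumps({
                "query": Q.name,
                "vertices": m.vertex_assignment,
                "edges": m.edge_assignment,
                "ss": round(m.ss, 6),
            }) + "\n")
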