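"""Recursive query splitting and the split-then-join search strategy.

Large queries are expensive to search directly.  The splitter decomposes a
query with more than 3 roles into two overlapping parts that share a single
overlap node (ON) -- the most connected role -- and recurses until every leaf
part has at most 3 roles.  The two parts are searched separately, seeded at
the ON (whose candidates are additionally constrained by the ON's degree in
the full query), partial matches sharing an ON image are joined, any query
edge spanning the parts is restored, and the closed-world and semantic checks
are re-applied to the joined mapping.  The result set is provably identical
to the plain search's.

Part searches deliberately relax two checks that only make sense on the full
mapping: the closed-world rule (a target edge between two part images may be
matched by an edge of the other part or by a residual edge) and, in
cumulative mode, the threshold (a part's mean says nothing about the full
mean); both are re-established on the joined mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .matcher import (
    Mapping,
    QueryEdge,
    QueryGraph,
    _edge_assignment_combos,
    _search_impl,
    induced_assignment_ok,
)
from .semantics import SDCMatrices, SearchConfig, _EPS
from .typed_graph import TypedGraph

__all__ = ["SplitResult", "split_once", "split_recursive", "split_search"]


@dataclass
class SplitResult:
    """Leaves of the recursive split, their seeding overlap nodes, and the
    query edges allocated to no part."""

    parts: list[QueryGraph]
    overlap_nodes: dict[str, str]
    residual_edges: list[QueryEdge] = field(default_factory=list)


def _undirected_view(Q: QueryGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(Q.roles)
    for e in Q.edges:
        g.add_edge(e.source, e.target)
    return g


def _lex_shortest_path(g: nx.Graph, start: str, goal: str) -> list[str]:
    """Minimum-hop path with the lexicographically smallest role-id sequence."""
    dist = nx.single_source_shortest_path_length(g, goal)
    path = [start]
    node = start
    while node != goal:
        node = min(n for n in g.neighbors(node) if dist.get(n, -1) == dist[node] - 1)
        path.append(node)
    return path


def split_once(Q: QueryGraph) -> tuple[QueryGraph, QueryGraph, str, list[QueryEdge]]:
    """One round of splitting: (D1, D2, overlap node, residual edges).

    The overlap node is the maximum-degree role of the undirected view (ties:
    minimum eccentricity, then smallest id); the two most distant remaining
    roles seed the parts through their shortest paths to the overlap node;
    every other role joins the part holding more of its already-allocated
    neighbors (ties: the smaller part, then D1).
    """
    if Q.num_vertices() < 4:
        raise ValueError("split_once requires a query with at least 4 roles")
    g = _undirected_view(Q)
    ecc = nx.eccentricity(g)
    on = min(Q.roles, key=lambda r: (-Q.degree(r), ecc[r], r))

    remaining = sorted(set(Q.roles) - {on})
    dist = dict(nx.all_pairs_shortest_path_length(g))
    best_pair, best_d = None, -1
    for i, a in enumerate(remaining):
        for b in remaining[i + 1:]:
            d = dist[a][b]
            if d > best_d:
                best_d, best_pair = d, (a, b)
    v1, v2 = best_pair

    part1 = set(_lex_shortest_path(g, v1, on))
    part2 = set(_lex_shortest_path(g, v2, on))

    unallocated = set(Q.roles) - part1 - part2
    while unallocated:
        counts = {}
        for r in unallocated:
            nbrs = set(g.neighbors(r))
            counts[r] = (len(nbrs & part1), len(nbrs & part2))
        # allocate the role with the most already-allocated neighbors first
        r = min(unallocated, key=lambda x: (-(counts[x][0] + counts[x][1]), x))
        c1, c2 = counts[r]
        if c1 + c2 == 0:  # cannot happen for connected queries
            raise AssertionError("unallocatable role in a connected query")
        if c1 > c2:
            part1.add(r)
        elif c2 > c1:
            part2.add(r)
        elif len(part1) <= len(part2):
            part1.add(r)
        else:
            part2.add(r)
        unallocated.discard(r)

    e1, e2, residual = [], [], []
    for e in Q.edges:
        if e.source in part1 and e.target in part1:
            e1.append(e)
        elif e.source in part2 and e.target in part2:
            e2.append(e)
        else:
            residual.append(e)

    D1 = QueryGraph({r: Q.roles[r] for r in part1}, e1, name=f"{Q.name or 'q'}/1")
    D2 = QueryGraph({r: Q.roles[r] for r in part2}, e2, name=f"{Q.name or 'q'}/2")
    return D1, D2, on, residual


def split_recursive(Q: QueryGraph) -> SplitResult:
    """Split until every leaf part has at most 3 roles."""
    if Q.num_vertices() <= 3:
        return SplitResult([Q], {})
    D1, D2, on, residual = split_once(Q)
    result = SplitResult([], {}, list(residual))
    for part in (D1, D2):
        if part.num_vertices() <= 3:
            result.parts.append(part)
            result.overlap_nodes[part.name] = on
        else:
            sub = split_recursive(part)
            result.parts.extend(sub.parts)
            result.residual_edges.extend(sub.residual_edges)
            for name, sub_on in sub.overlap_nodes.items():
                result.overlap_nodes[name] = sub_on
            for leaf in sub.parts:
                result.overlap_nodes.setdefault(leaf.name, on)
    return result


def _part_assignments(
    G: TypedGraph,
    part: QueryGraph,
    matrices: SDCMatrices,
    cfg: SearchConfig,
    n_full: int,
    role_min_degree: dict[str, int],
    role_domains: dict[str, set[str]],
    anchor: str,
) -> list[dict[str, str]]:
    """Distinct vertex assignments of a part, searched non-induced with
    thresholds deferred to the joined mapping; recurses through further splits."""
    # caps, orbit collapsing and the strict-degree variant only make sense on
    # the full mapping; never apply them inside a part
    cfg = replace(cfg, strict_degree=False, max_mappings=None, dedup_orbits=False)
    if part.num_vertices() <= 3:
        found = _search_impl(
            G, part, matrices, cfg,
            induced=False,
            role_min_degree=role_min_degree,
            role_domains=role_domains,
            total_elements=n_full,
            anchor_role=anchor,
        )
        seen, out = set(), []
        for m in found:
            key = tuple(sorted(m.vertex_assignment.items()))
            if key not in seen:
                seen.add(key)
                out.append(m.vertex_assignment)
        return out

    D1, D2, on, residual = split_once(part)
    sub_min = dict(role_min_degree)
    sub_min[on] = max(sub_min.get(on, 0), part.degree(on))
    first, second = (D1, D2) if D1.num_vertices() <= D2.num_vertices() else (D2, D1)

    def restrict(d: dict, roles) -> dict:
        return {r: v for r, v in d.items() if r in roles}

    first_found = _part_assignments(
        G, first, matrices, cfg, n_full,
        restrict(sub_min, first.roles), restrict(role_domains, first.roles), on)
    on_images = {a[on] for a in first_found}
    second_domains = restrict(role_domains, second.roles)
    second_domains[on] = second_domains.get(on, on_images) & on_images
    second_found = _part_assignments(
        G, second, matrices, cfg, n_full,
        restrict(sub_min, second.roles), second_domains, on)

    return _join(G, cfg, matrices, first, second, first_found, second_found, residual)


def _join(G, cfg, matrices, first, second, first_found, second_found, residual,
          ) -> list[dict[str, str]]:
    """Join part assignments sharing the overlap image(s), require global
    injectivity, and keep only joins whose residual edges exist in G."""
    shared = sorted(set(first.roles) & set(second.roles))
    by_key: dict[tuple, list[dict[str, str]]] = {}
    for a in first_found:
        by_key.setdefault(tuple(a[r] for r in shared), []).append(a)
    joined, seen = [], set()
    for b in second_found:
        key = tuple(b[r] for r in shared)
        for a in by_key.get(key, []):
            only_a = {v for r, v in a.items() if r not in shared}
            only_b = {v for r, v in b.items() if r not in shared}
            if only_a & only_b:
                continue
            merged = {**a, **b}
            mkey = tuple(sorted(merged.items()))
            if mkey in seen:
                continue
            ok = True
            for e in residual:
                need = sum(1 for f in residual
                           if (f.source, f.target) == (e.source, e.target))
                if G.count_edges_directed(merged[e.source], merged[e.target]) < need:
                    ok = False
                    break
            if ok:
                seen.add(mkey)
                joined.append(merged)
    return joined


def split_search(
    G: TypedGraph,
    Q: QueryGraph,
    matrices: SDCMatrices,
    cfg: SearchConfig | None = None,
) -> list[Mapping]:
    """Search via recursive splitting; returns exactly the plain search's
    mapping set.  Queries with at most 3 roles delegate to the plain search."""
    from .matcher import search

    cfg = cfg or SearchConfig()
    if Q.num_vertices() <= 3:
        return search(G, Q, matrices, cfg)

    n_full = Q.num_vertices() + Q.num_edges()
    D1, D2, on, residual = split_once(Q)
    sub_min = {on: Q.degree(on)}
    first, second = (D1, D2) if D1.num_vertices() <= D2.num_vertices() else (D2, D1)

    first_found = _part_assignments(
        G, first, matrices, cfg, n_full,
        {r: d for r, d in sub_min.items() if r in first.roles}, {}, on)
    on_images = {a[on] for a in first_found}
    second_found = _part_assignments(
        G, second, matrices, cfg, n_full,
        {r: d for r, d in sub_min.items() if r in second.roles}, {on: on_images}, on)

    joined = _join(G, cfg, matrices, first, second, first_found, second_found, residual)

    # full-mapping re-checks: closed world, edge assignment, threshold, score
    results: list[Mapping] = []
    seen_orbits: set = set()
    per_elem = cfg.mode == "per_element"
    for assignment in joined:
        if not induced_assignment_ok(G, Q, assignment):
            continue
        vscore_sum = sum(matrices.score_vertex(Q.roles[r], G.vertex_type(v))
                         for r, v in assignment.items())
        if per_elem and any(
            matrices.score_vertex(Q.roles[r], G.vertex_type(v)) < cfg.st - _EPS
            for r, v in assignment.items()
        ):
            continue
        if cfg.strict_degree and any(
            G.degree(v, "total") != Q.degree(r) for r, v in assignment.items()
        ):
            continue
        for edge_assignment, escore_sum in _edge_assignment_combos(
            G, Q, matrices, cfg.st, per_elem, assignment
        ):
            total = vscore_sum + escore_sum
            ss = total / n_full
            if cfg.mode == "cumulative" and ss < cfg.st - _EPS:
                continue
            if cfg.dedup_orbits:
                orbit = (frozenset(assignment.values()),
                         frozenset(edge_assignment.values()))
                if orbit in seen_orbits:
                    continue
                seen_orbits.add(orbit)
            results.append(Mapping(dict(assignment), edge_assignment, ss))
            if cfg.max_mappings is not None and len(results) >= cfg.max_mappings:
                return results
    return results
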