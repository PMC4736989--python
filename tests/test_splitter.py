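import pytest

import semmine as sm
from semmine.matcher import QueryEdge, QueryGraph, brute_force_search, search
from semmine.splitter import split_once, split_recursive, split_search

from conftest import ETYPES, VTYPES, random_instance


def path_query(n, vtype="Compound", etype="similar_to"):
    roles = {f"v{i}": vtype for i in range(1, n + 1)}
    edges = [QueryEdge(f"q{i}", f"v{i}", f"v{i+1}", etype) for i in range(1, n)]
    return QueryGraph(roles, edges)


def test_split_once_on_a_five_path_picks_the_centre():
    D1, D2, on, residual = split_once(path_query(5))
    assert on == "v3"  # degree tie broken by minimum eccentricity
    assert set(D1.roles) == {"v1", "v2", "v3"}
    assert set(D2.roles) == {"v3", "v4", "v5"}
    assert residual == []


def test_split_once_rejects_small_queries():
    with pytest.raises(ValueError):
        split_once(path_query(3))


def test_triangle_plus_pendant_keeps_parts_connected():
    Q = QueryGraph({"a": "Compound", "b": "Compound", "c": "Compound", "d": "Target"},
                   [QueryEdge("q1", "a", "b", "similar_to"),
                    QueryEdge("q2", "b", "c", "similar_to"),
                    QueryEdge("q3", "c", "a", "similar_to"),
                    QueryEdge("q4", "a", "d", "binds_to")])
    D1, D2, on, residual = split_once(Q)
    assert on == "a"  # unique max degree
    for part in (D1, D2):
        assert part.is_connected()
        assert on in part.roles
    allocated = {e.id for e in D1.edges} | {e.id for e in D2.edges} | \
        {e.id for e in residual}
    assert allocated == {"q1", "q2", "q3", "q4"}


def test_recursive_split_six_path_gives_small_leaves():
    result = split_recursive(path_query(6))
    sizes = sorted(p.num_vertices() for p in result.parts)
    assert max(sizes) <= 3
    assert set().union(*[set(p.roles) for p in result.parts]) == \
        {f"v{i}" for i in range(1, 7)}


def test_trivial_split_below_four_roles():
    Q = path_query(3)
    result = split_recursive(Q)
    assert len(result.parts) == 1
    assert result.parts[0] is Q
    assert result.residual_edges == []


@pytest.mark.parametrize("n", [6, 7, 8, 9])
@pytest.mark.parametrize("seed", range(6))
def test_recursive_split_invariants_on_random_queries(n, seed):
    Q = sm.random_query(n, VTYPES, ETYPES, extra_edges=seed % 3, seed=seed * 17 + n)
    result = split_recursive(Q)
    assert max(p.num_vertices() for p in result.parts) <= 3
    assert set().union(*[set(p.roles) for p in result.parts]) == set(Q.roles)
    allocated = sorted([e.id for p in result.parts for e in p.edges] +
                       [e.id for e in result.residual_edges])
    assert allocated == sorted(e.id for e in Q.edges)
    for part in result.parts:
        assert part.is_connected()


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("mode", ["per_element", "cumulative"])
def test_split_search_equals_plain_search(seed, mode):
    n_q = 4 + seed % 4
    G, Q, M = random_instance(seed, n_g=26, n_q=n_q, extra=seed % 3)
    cfg = sm.SearchConfig(mode=mode, st=0.8, prune_enabled=False)
    assert set(split_search(G, Q, M, cfg)) == set(search(G, Q, M, cfg))


def test_four_cycle_residual_edges_are_verified():
    # a 4-cycle splits into two paths; the closing edges are residual and a
    # join lacking them must be rejected
    Q = QueryGraph({"a": "Compound", "b": "Target", "c": "Compound", "d": "Target"},
                   [QueryEdge("q1", "a", "b", "binds_to"),
                    QueryEdge("q2", "b", "c", "binds_to"),
                    QueryEdge("q3", "c", "d", "binds_to"),
                    QueryEdge("q4", "d", "a", "binds_to")])
    from semmine.typed_graph import EdgeRecord, TypedGraph, VertexRecord
    g = TypedGraph()
    for i in range(4):
        g.add_vertex(VertexRecord(f"c{i}", "Compound"))
        g.add_vertex(VertexRecord(f"t{i}", "Target"))
    # one true 4-cycle ...
    g.add_edge(EdgeRecord("e1", "c0", "t0", "binds_to"))
    g.add_edge(EdgeRecord("e2", "t0", "c1", "binds_to"))
    g.add_edge(EdgeRecord("e3", "c1", "t1", "binds_to"))
    g.add_edge(EdgeRecord("e4", "t1", "c0", "binds_to"))
    # ... and an open path that must not yield a mapping
    g.add_edge(EdgeRecord("e5", "c2", "t2", "binds_to"))
    g.add_edge(EdgeRecord("e6", "t2", "c3", "binds_to"))
    g.add_edge(EdgeRecord("e7", "c3", "t3", "binds_to"))
    m = sm.identity_sdc({"Compound", "Target"}, {"binds_to"})
    cfg = sm.SearchConfig(prune_enabled=False)
    found = split_search(g, Q, m, cfg)
    assert set(found) == set(brute_force_search(g, Q, m, cfg))
    assert {tuple(sorted(mp.vertex_assignment.values())) for mp in found} == \
        {("c0", "c1", "t0", "t1")}


def test_split_search_delegates_for_small_queries():
    G, Q, M = random_instance(4, n_g=24, n_q=3, extra=0)
    cfg = sm.SearchConfig(prune_enabled=False)
    assert set(split_search(G, Q, M, cfg)) == set(search(G, Q, M, cfg))
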