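import pytest

import semmine as sm
from semmine.matcher import (Mapping, OracleSizeError, QueryEdge, QueryGraph,
                             brute_force_search, initial_candidates, load_query,
                             mappings_to_inferences, save_query, search,
                             select_anchor)
from semmine.typed_graph import EdgeRecord, TypedGraph, VertexRecord

from conftest import ETYPES, VTYPES, random_instance


# -- query model -----------------------------------------------------------

def test_query_requires_connectivity_and_two_roles():
    with pytest.raises(ValueError):
        QueryGraph({"a": "Compound"}, [])
    with pytest.raises(ValueError):
        QueryGraph({"a": "Compound", "b": "Target", "c": "Target"},
                   [QueryEdge("q1", "a", "b", "binds_to")])  # c disconnected


def test_query_json_round_trip(tmp_path):
    _, Q = sm.chlorpromazine_fixture()
    save_query(Q, tmp_path / "q.json")
    back = load_query(tmp_path / "q.json")
    assert back.roles == Q.roles
    assert [(e.source, e.target, e.type) for e in back.edges] == \
           [(e.source, e.target, e.type) for e in Q.edges]
    assert back.inference == Q.inference


# -- anchor selection ------------------------------------------------------

def test_anchor_prefers_max_degree_of_anchor_type():
    Q = QueryGraph({"A": "Compound", "B": "Compound", "t": "Target"},
                   [QueryEdge("q1", "A", "B", "similar_to"),
                    QueryEdge("q2", "B", "t", "binds_to")])
    assert select_anchor(Q, "Compound") == "B"


def test_anchor_tie_breaks_lexicographically():
    Q = QueryGraph({"c1": "Compound", "c2": "Compound"},
                   [QueryEdge("q1", "c1", "c2", "similar_to")])
    assert select_anchor(Q, "Compound") == "c1"


def test_anchor_falls_back_with_warning():
    Q = QueryGraph({"p": "Protein", "t": "Target", "d": "Disease"},
                   [QueryEdge("q1", "p", "t", "similar_to"),
                    QueryEdge("q2", "t", "d", "involved_in")])
    with pytest.warns(UserWarning, match="anchor type"):
        assert select_anchor(Q, "Compound") == "t"  # max degree globally


def test_initial_candidates_filter_type_and_degree(identity_matrices):
    G, Q = sm.chlorpromazine_fixture()
    cfg = sm.SearchConfig()
    m = sm.identity_sdc(G.vertex_type_vocabulary, G.edge_type_vocabulary)
    anchor = select_anchor(Q, "Compound")  # C2, degree 2
    cands = initial_candidates(G, Q, anchor, m, cfg)
    # both compounds have total degree >= 2; targets are semantically excluded
    assert set(cands) == {"chlorpromazine", "trimeprazine"}


# -- the worked example ----------------------------------------------------

def test_fixture_search_finds_the_single_guilt_by_association_mapping():
    G, Q = sm.chlorpromazine_fixture()
    m = sm.identity_sdc(G.vertex_type_vocabulary, G.edge_type_vocabulary)
    found = search(G, Q, m, sm.SearchConfig())
    assert len(found) == 1
    assert found[0].vertex_assignment == {
        "C1": "chlorpromazine", "C2": "trimeprazine", "T": "Histamine H1 receptor"}
    assert found[0].ss == 1.0
    assert mappings_to_inferences(found, Q) == \
        [("chlorpromazine", "Histamine H1 receptor")]


def test_closed_world_rejects_mapping_with_extra_edge():
    G, Q = sm.chlorpromazine_fixture()
    G = G.copy()
    G.add_edge(EdgeRecord("extra", "chlorpromazine", "Histamine H1 receptor",
                          "binds_to"))
    m = sm.identity_sdc(G.vertex_type_vocabulary, G.edge_type_vocabulary)
    assert search(G, Q, m, sm.SearchConfig()) == []
    assert brute_force_search(G, Q, m, sm.SearchConfig()) == []


def test_empty_target_graph_gives_no_mappings(identity_matrices):
    _, Q = sm.chlorpromazine_fixture()
    m = sm.identity_sdc({"Compound", "Target"}, {"binds_to", "similar_to"})
    g = TypedGraph()
    assert search(g, Q, m, sm.SearchConfig()) == []


# -- oracle equivalence ----------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("mode", ["per_element", "cumulative"])
def test_search_matches_brute_force_on_random_instances(seed, mode):
    n_q = 3 + seed % 4
    G, Q, M = random_instance(seed, n_g=24, n_q=n_q, extra=seed % 2)
    cfg = sm.SearchConfig(mode=mode, st=0.8, split_enabled=False,
                          prune_enabled=False)
    assert set(search(G, Q, M, cfg)) == set(brute_force_search(G, Q, M, cfg))


def test_oracle_guard_rejects_large_graphs(identity_matrices):
    G, Q, M = random_instance(0, n_g=90, n_q=3, extra=0)
    with pytest.raises(OracleSizeError):
        brute_force_search(G, Q, M, sm.SearchConfig())


def test_query_larger_than_target_is_empty():
    g = TypedGraph()
    g.add_vertex(VertexRecord("a", "Compound"))
    g.add_vertex(VertexRecord("b", "Compound"))
    g.add_edge(EdgeRecord("e1", "a", "b", "similar_to"))
    Q = QueryGraph({f"v{i}": "Compound" for i in range(3)},
                   [QueryEdge("q1", "v0", "v1", "similar_to"),
                    QueryEdge("q2", "v1", "v2", "similar_to")])
    m = sm.identity_sdc({"Compound"}, {"similar_to"})
    assert brute_force_search(g, Q, m, sm.SearchConfig()) == []


def test_networkx_induced_isomorphism_agrees_on_vertex_assignments():
    """Independent cross-check: at full semantic identity the mapping set's
    vertex assignments coincide with networkx's node-induced subgraph
    isomorphisms on the typed multigraph."""
    import networkx as nx
    from networkx.algorithms import isomorphism as iso

    G, Q, M = random_instance(3, n_g=24, n_q=3, extra=0)
    cfg = sm.SearchConfig(st=1.0, mode="per_element", split_enabled=False,
                          prune_enabled=False)
    ours = {tuple(sorted(m.vertex_assignment.items()))
            for m in search(G, Q, M, cfg)}

    qg = nx.MultiDiGraph()
    for r, t in Q.roles.items():
        qg.add_node(r, type=t)
    for e in Q.edges:
        qg.add_edge(e.source, e.target, type=e.type)
    gm = iso.MultiDiGraphMatcher(
        G.nx, qg,
        node_match=iso.categorical_node_match("type", None),
        edge_match=iso.categorical_multiedge_match("type", None))
    theirs = {tuple(sorted((role, vid) for vid, role in m.items()))
              for m in gm.subgraph_isomorphisms_iter()}
    assert ours == theirs


# -- search properties -----------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_returned_mappings_are_induced(seed):
    G, Q, M = random_instance(seed, n_g=24, n_q=4, extra=1)
    from semmine.matcher import induced_assignment_ok
    for m in search(G, Q, M, sm.SearchConfig(split_enabled=False,
                                             prune_enabled=False)):
        assert induced_assignment_ok(G, Q, m.vertex_assignment)


@pytest.mark.parametrize("mode", ["per_element", "cumulative"])
def test_raising_threshold_never_adds_mappings(mode):
    G, Q, M = random_instance(1, n_g=24, n_q=3, extra=0)
    prev = None
    for st in (0.0, 0.5, 0.8, 1.0):
        cfg = sm.SearchConfig(st=st, mode=mode, split_enabled=False,
                              prune_enabled=False)
        found = set(search(G, Q, M, cfg))
        if prev is not None:
            assert found <= prev
        prev = found


def test_planted_disjoint_instances_add_exactly_k():
    G, _, M = random_instance(2, n_g=30)
    Q = sm.random_query(4, ["Compound", "Target", "Protein", "Disease"],
                        ETYPES, extra_edges=1, seed=77)
    cfg = sm.SearchConfig(split_enabled=False, prune_enabled=False)
    base = len(search(G, Q, M, cfg))
    spiked = sm.plant_instances(G, Q, 5, seed=3)
    assert len(search(spiked, Q, M, cfg)) == base + 5


def test_parallel_query_edges_map_to_distinct_target_edges():
    g = TypedGraph()
    g.add_vertex(VertexRecord("a", "Compound"))
    g.add_vertex(VertexRecord("b", "Target"))
    g.add_edge(EdgeRecord("e1", "a", "b", "binds_to"))
    g.add_edge(EdgeRecord("e2", "a", "b", "binds_to"))
    Q = QueryGraph({"c": "Compound", "t": "Target"},
                   [QueryEdge("q1", "c", "t", "binds_to"),
                    QueryEdge("q2", "c", "t", "binds_to")])
    m = sm.identity_sdc({"Compound", "Target"}, {"binds_to"})
    found = search(g, Q, m, sm.SearchConfig())
    # two permutations of the parallel pair, each injective on edges
    assert len(found) == 2
    for mp in found:
        assert len(set(mp.edge_assignment.values())) == 2
    dedup = search(g, Q, m, sm.SearchConfig(dedup_orbits=True))
    assert len(dedup) == 1


def test_query_self_loop_requires_target_self_loop():
    g = TypedGraph()
    g.add_vertex(VertexRecord("a", "Compound"))
    g.add_vertex(VertexRecord("b", "Compound"))
    g.add_edge(EdgeRecord("e1", "a", "a", "similar_to"))
    g.add_edge(EdgeRecord("e2", "a", "b", "similar_to"))
    Q = QueryGraph({"x": "Compound", "y": "Compound"},
                   [QueryEdge("q1", "x", "x", "similar_to"),
                    QueryEdge("q2", "x", "y", "similar_to")])
    m = sm.identity_sdc({"Compound"}, {"similar_to"})
    found = search(g, Q, m, sm.SearchConfig(anchor_type="Compound"))
    assert len(found) == 1
    assert found[0].vertex_assignment == {"x": "a", "y": "b"}
    assert set(found) == set(brute_force_search(g, Q, m, sm.SearchConfig()))


def test_max_mappings_caps_results():
    G, _, M = random_instance(2, n_g=30)
    Q = QueryGraph({"c1": "Compound", "c2": "Compound"},
                   [QueryEdge("q1", "c1", "c2", "similar_to")])
    cfg = sm.SearchConfig(split_enabled=False, prune_enabled=False)
    total = len(search(G, Q, M, cfg))
    assert total > 2
    capped = search(G, Q, M, sm.SearchConfig(split_enabled=False,
                                             prune_enabled=False, max_mappings=2))
    assert len(capped) == 2


def test_inference_extraction_requires_annotation():
    _, Q = sm.chlorpromazine_fixture()
    bare = QueryGraph(Q.roles, Q.edges)  # no inference
    with pytest.raises(ValueError):
        mappings_to_inferences([], bare)
    assert mappings_to_inferences([], Q) == []
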