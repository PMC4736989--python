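import pytest

import semmine as sm
from semmine.derivation import (NoPathError, dedup_queries, derive_queries,
                                path_to_query, relevant_interactions,
                                shortest_semantic_path)
from semmine.matcher import QueryEdge, QueryGraph
from semmine.typed_graph import EdgeRecord, TypedGraph, VertexRecord


def chain_graph():
    g = TypedGraph()
    for vid, t in [("a", "Compound"), ("c", "Compound"), ("b", "Target"),
                   ("x", "Target"), ("y", "Disease")]:
        g.add_vertex(VertexRecord(vid, t))
    g.add_edge(EdgeRecord("e1", "a", "c", "similar_to"))
    g.add_edge(EdgeRecord("e2", "c", "b", "binds_to"))
    g.add_edge(EdgeRecord("e3", "b", "y", "involved_in"))
    g.add_edge(EdgeRecord("e4", "c", "x", "binds_to"))
    return g


def test_relevant_keeps_only_unlinked_pairs_present_in_graph():
    g = chain_graph()
    candidates = [("a", "b"),   # both present, no binds_to edge -> kept
                  ("c", "b"),   # existing binds_to edge -> dropped
                  ("zz", "b")]  # absent drug -> dropped
    rel = relevant_interactions(g, candidates, "binds_to")
    assert rel.pairs == {("a", "b")}


def test_shortest_path_reports_stored_directions_and_types():
    g = chain_graph()
    vertices, edges = shortest_semantic_path(g, "a", "b")
    assert [v.id for v in vertices] == ["a", "c", "b"]
    assert [(e.source, e.target, e.type) for e in edges] == \
        [("a", "c", "similar_to"), ("c", "b", "binds_to")]


def test_shortest_path_tie_breaks_lexicographically():
    g = TypedGraph()
    for vid in ["s", "m1", "m2", "e"]:
        g.add_vertex(VertexRecord(vid, "Compound"))
    g.add_edge(EdgeRecord("e1", "s", "m1", "similar_to"))
    g.add_edge(EdgeRecord("e2", "s", "m2", "similar_to"))
    g.add_edge(EdgeRecord("e3", "m1", "e", "similar_to"))
    g.add_edge(EdgeRecord("e4", "m2", "e", "similar_to"))
    vertices, _ = shortest_semantic_path(g, "s", "e")
    assert [v.id for v in vertices] == ["s", "m1", "e"]


def test_no_path_raises():
    g = chain_graph()
    g.add_vertex(VertexRecord("island", "Compound"))
    with pytest.raises(NoPathError):
        shortest_semantic_path(g, "a", "island")


def test_path_to_query_builds_typed_roles_with_inference():
    g = chain_graph()
    Q = path_to_query(shortest_semantic_path(g, "a", "b"), "binds_to")
    assert list(Q.roles.values()) == ["Compound", "Compound", "Target"]
    assert [(e.source, e.target, e.type) for e in Q.edges] == \
        [("r0", "r1", "similar_to"), ("r1", "r2", "binds_to")]
    assert Q.inference == ("r0", "r2", "binds_to")


def test_path_to_query_keeps_repeated_types_as_distinct_roles():
    g = TypedGraph()
    for vid, t in [("c1", "Compound"), ("t1", "Target"), ("c2", "Compound")]:
        g.add_vertex(VertexRecord(vid, t))
    g.add_edge(EdgeRecord("e1", "c1", "t1", "binds_to"))
    g.add_edge(EdgeRecord("e2", "c2", "t1", "binds_to"))
    Q = path_to_query(shortest_semantic_path(g, "c1", "c2"), "similar_to")
    assert Q.num_vertices() == 3
    assert list(Q.roles.values()) == ["Compound", "Target", "Compound"]


def test_zero_length_path_rejected():
    g = chain_graph()
    with pytest.raises(ValueError):
        path_to_query(([g.vertex("a")], []), "binds_to")


def make_triad(name, flip=False):
    src, dst = ("r1", "r0") if flip else ("r0", "r1")
    return QueryGraph({"r0": "Compound", "r1": "Compound", "r2": "Target"},
                      [QueryEdge("qe0", src, dst, "similar_to"),
                       QueryEdge("qe1", "r1", "r2", "binds_to")],
                      inference=("r0", "r2", "binds_to"), name=name)


def test_dedup_groups_isomorphic_queries():
    queries = [make_triad("a"), make_triad("b"),
               make_triad("c").relabeled({"r0": "x", "r1": "y", "r2": "z"})]
    classes = dedup_queries(queries)
    assert len(classes) == 1
    assert classes[0][1] == 3


def test_dedup_distinguishes_edge_direction():
    classes = dedup_queries([make_triad("fwd"), make_triad("rev", flip=True)])
    assert sorted(c for _, c in classes) == [1, 1]


def test_dedup_multiplicities_sum_and_size_cap():
    big = sm.random_query(10, ["Compound"] * 10, ["similar_to"], seed=1)
    with pytest.warns(UserWarning, match="discarding"):
        classes = dedup_queries([make_triad("a"), make_triad("b"), big],
                                max_vertices=9)
    assert sum(c for _, c in classes) == 2
    assert dedup_queries([]) == []


def test_derive_queries_end_to_end_reproduces_the_two_hop_template():
    g = chain_graph()
    rel = relevant_interactions(g, [("a", "b"), ("a", "x")], "binds_to")
    classes, skipped = derive_queries(g, rel, "binds_to")
    assert skipped == []
    # both pairs route through c with identical type sequences -> one class
    assert len(classes) == 1
    Q, mult = classes[0]
    assert mult == 2
    assert list(Q.roles.values()) == ["Compound", "Compound", "Target"]
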