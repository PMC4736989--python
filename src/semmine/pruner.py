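"""Semantic graph pruning.

Before a search, target vertices whose types are semantically distant from
every query vertex type can be removed, together with their incident edges;
vertices left isolated by the edge removal are discarded as well.  A target
type survives iff its best score against any query vertex type reaches the
threshold (a type close to any query type may still participate in a match).

In per-element mode pruning never changes the search result: every vertex of
a surviving mapping scores at least the threshold against its own query role.
In cumulative mode a high-scoring mapping may absorb a below-threshold
element, which pruning would have removed, so pruning defaults off there.
"""

from __future__ import annotations

from .matcher import QueryGraph
from .semantics import SDCMatrices, _EPS
from .typed_graph import TypedGraph

__all__ = ["semantic_prune"]


def semantic_prune(
    G: TypedGraph, Q: QueryGraph, matrices: SDCMatrices, st: float
) -> TypedGraph:
    """Return a pruned copy of G; the input graph is never modified."""
    query_types = set(Q.roles.values())
    surviving_types = {
        t for t in G.vertex_type_vocabulary
        if max(matrices.score_vertex(q, t) for q in query_types) >= st - _EPS
    }
    out = TypedGraph()
    for v in G.vertices():
        if v.type in surviving_types:
            out.add_vertex(v)
    for e in G.edges():
        if e.source in out and e.target in out:
            out.add_edge(e)
    isolated = [v for v in out.vertex_ids() if out.degree(v, "total") == 0]
    if isolated:
        survivors = set(out.vertex_ids()) - set(isolated)
        trimmed = TypedGraph()
        for v in out.vertices():
            if v.id in survivors:
                trimmed.add_vertex(v)
        for e in out.edges():
            trimmed.add_edge(e)
        return trimmed
    return out
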