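"""Scoring queries by recovery of known interactions and ranking inferences.

A query's recovery score R_q is the fraction of its unique inferred
drug-target pairs that appear in the reference set of known interactions.
Each inferred interaction i is then scored by the cumulative confidence
R_i = sum of R_q over the queries that inferred it, and the interactions are
ranked by descending R_i.  Interactions already present as edges in the
mined network are excluded from the ranked output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .derivation import ReferenceInteractionSet
from .typed_graph import TypedGraph

__all__ = [
    "QueryScore",
    "InferredInteraction",
    "score_query",
    "score_interactions",
    "rank_interactions",
    "write_ranked_tsv",
]


@dataclass
class QueryScore:
    query_id: str
    rq: float
    inferred_unique: set[tuple[str, str]]
    n_known: int


@dataclass
class InferredInteraction:
    drug: str
    target: str
    ri: float
    supporting_queries: set[str] = field(default_factory=set)


def score_query(
    inferred, reference: ReferenceInteractionSet, query_id: str = "q"
) -> QueryScore:
    """R_q = |unique inferred pairs that are known| / |unique inferred pairs|.

    Raw inferences are deduplicated to a set first; a query with no
    inferences scores 0."""
    unique = set(inferred)
    known = unique & reference.pairs
    rq = len(known) / len(unique) if unique else 0.0
    return QueryScore(query_id, rq, unique, len(known))


def score_interactions(
    per_query_inferences: dict[str, list[tuple[str, str]]],
    scores: list[QueryScore],
) -> list[InferredInteraction]:
    """R_i(i) = sum of R_q over queries whose unique inference set contains i.

    A pair inferred several times by the same query counts once for that
    query."""
    score_of = {s.query_id: s for s in scores}
    interactions: dict[tuple[str, str], InferredInteraction] = {}
    for qid, inferred in per_query_inferences.items():
        if qid not in score_of:
            raise KeyError(f"no score for query {qid!r}")
        rq = score_of[qid].rq
        for pair in set(inferred):
            it = interactions.get(pair)
            if it is None:
                it = interactions[pair] = InferredInteraction(pair[0], pair[1], 0.0)
            if qid not in it.supporting_queries:
                it.supporting_queries.add(qid)
                it.ri += rq
    return list(interactions.values())


def rank_interactions(
    interactions, G: TypedGraph | None = None, interaction_edge_type: str | None = None
) -> list[InferredInteraction]:
    """Descending by R_i; ties by descending supporter count, then drug id,
    then target id.  With ``G`` given, pairs already joined by an edge of
    ``interaction_edge_type`` are dropped (closed-world makes this a
    belt-and-braces filter)."""
    items = list(interactions)
    if G is not None and interaction_edge_type is not None:
        items = [
            it for it in items
            if it.drug not in G or it.target not in G
            or not any(e.type == interaction_edge_type
                       for e in G.edges_between(it.drug, it.target))
        ]
    return sorted(items, key=lambda it: (-it.ri, -len(it.supporting_queries),
                                         it.drug, it.target))


def write_ranked_tsv(ranked, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rank", "drug_id", "target_id", "ri",
                    "n_supporting_queries", "supporting_query_ids"])
        for i, it in enumerate(ranked, start=1):
            w.writerow([i, it.drug, it.target, f"{it.ri:.5f}",
                        len(it.supporting_queries),
                        ",".join(sorted(it.supporting_queries))])
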