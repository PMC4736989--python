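"""End-to-end orchestration: prune, search (split or plain), infer, rank."""

from __future__ import annotations

import logging

from .derivation import ReferenceInteractionSet
from .matcher import Mapping, QueryGraph, mappings_to_inferences, search
from .pruner import semantic_prune
from .ranking import (InferredInteraction, rank_interactions, score_interactions,
                      score_query)
from .semantics import SDCMatrices, SearchConfig
from .splitter import split_search
from .typed_graph import TypedGraph

__all__ = ["mine_query", "mine_and_rank"]

log = logging.getLogger("semmine")


def mine_query(
    G: TypedGraph,
    Q: QueryGraph,
    matrices: SDCMatrices,
    cfg: SearchConfig | None = None,
) -> list[Mapping]:
    """Run the configured pipeline for one query: optional semantic pruning,
    then the split-and-join search for queries with more than 3 roles (when
    enabled), else the plain search."""
    cfg = cfg or SearchConfig()
    target = G
    if cfg.prune_enabled:
        target = semantic_prune(G, Q, matrices, cfg.st)
        log.info("prune: |V| %d -> %d, |E| %d -> %d", G.num_vertices(),
                 target.num_vertices(), G.num_edges(), target.num_edges())
    if cfg.split_enabled and Q.num_vertices() >= 4:
        found = split_search(target, Q, matrices, cfg)
    else:
        found = search(target, Q, matrices, cfg)
    log.info("query %s: %d mappings", Q.name or "?", len(found))
    return found


def mine_and_rank(
    G: TypedGraph,
    queries,
    matrices: SDCMatrices,
    reference: ReferenceInteractionSet,
    cfg: SearchConfig | None = None,
    interaction_edge_type: str = "binds_to",
) -> list[InferredInteraction]:
    """Mine every query, score each by recovery of the reference set, rank
    all inferred interactions by cumulative confidence."""
    cfg = cfg or SearchConfig()
    per_query: dict[str, list[tuple[str, str]]] = {}
    scores = []
    for i, Q in enumerate(queries):
        qid = Q.name or f"q{i}"
        mappings = mine_query(G, Q, matrices, cfg)
        inferred = mappings_to_inferences(mappings, Q) if Q.inference else []
        per_query[qid] = inferred
        scores.append(score_query(inferred, reference, qid))
    interactions = score_interactions(per_query, scores)
    return rank_interactions(interactions, G, interaction_edge_type)
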