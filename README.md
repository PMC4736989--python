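# semmine

Exhaustive mining of typed, directed, attributed multigraphs ("semantic
networks") for occurrences of small typed query subgraphs, and inference of
putative drug–target interactions from the mappings found.

Integrated drug-discovery networks represent compounds, protein targets,
diseases and their relationships as a typed multigraph: vertices carry types
such as `Compound` or `Target`, edges carry types such as `binds_to` or
`similar_to`. Local patterns in such a network — for example *a compound
structurally similar to a compound with a known target* — are indicative of
repositioning opportunities. semmine turns such patterns into **semantic
query subgraphs** and finds every embedding of them in the network, so that
candidate interactions can be enumerated, scored, and ranked rather than
spotted by hand. The intended users are computational drug-discovery and
network-biology groups working with heterogeneous knowledge graphs.

## The method

A query `Q` is a small connected typed digraph with an optional *inference
annotation* — a (drug role, target role, edge type) triple naming the edge to
be inferred from each match. A **mapping** `M` embeds `Q` into the target
network `G`: an injective assignment of query roles to vertices and query
edges to distinct edges preserving direction. Three ingredients extend the
classical VF-style backtracking subgraph search:

- **Semantic distance.** Two square symmetric matrices score similarity
  between vertex types and between edge types: 1 (identical), 0 (unrelated),
  −1 (opposite), graded values in between. The semantic score of a mapping is
  the mean over its `|V(Q)| + |E(Q)|` elements,

  `SS(M) = ( Σ_k SDC(m_k, q_k) ) / (|V(Q)| + |E(Q)|)`,

  and a user threshold `ST ∈ [0,1]` is applied either *per element* (every
  element ≥ ST) or *cumulatively* (mean ≥ ST).
- **Closed-world rule.** Absence of an edge is treated as evidence of no
  relationship: a mapping is rejected if any edge exists between mapped
  vertices (or as a self-loop on one) without a query counterpart — matches
  are induced.
- **Search-space reduction.** The search starts from an *initial candidate
  set* of vertices of a designated anchor type (default `Compound`) with
  degree at least the anchor role's; semantically distant vertex types can be
  *pruned* from `G` beforehand; and queries with more than 3 roles are
  recursively *split* at their most connected role (the overlap node), the
  parts searched separately and joined, provably without changing the result
  set.

Queries are scored by their recovery of known interactions,
`R_q = |Q(I) ∩ known| / |Q(I)|` over the query's unique inferred pairs, and
each inferred interaction is ranked by the cumulative confidence
`R_i(i) = Σ_{i ∈ Q'(I)} R_q(Q')` over the queries that inferred it.

## Worked example

```sh
python examples/worked_example.py
```

```
graph: |V|=6, |E|=5
mappings found: 1
  roles -> vertices: {'C2': 'trimeprazine', 'C1': 'chlorpromazine', 'T': 'Histamine H1 receptor'}   SS=1.0
inferred interaction: ('chlorpromazine', 'Histamine H1 receptor')
query recovery score Rq = 1.0
top-ranked interaction: chlorpromazine -> Histamine H1 receptor (Ri = 1.0)
```

The network holds chlorpromazine with three annotated targets, none
explaining its antihistaminic effect, and a structural-similarity edge to
trimeprazine, which binds the Histamine H1 receptor. The triad query
(compound —similar_to→ compound —binds_to→ target) matches exactly once with
a perfect semantic score, and the inference annotation reads off the
repositioning candidate: chlorpromazine binds the H1 receptor. Scoring the
query against a reference containing that pair gives `Rq = 1` (all its
unique inferences are known) and the pair ranks first with `Ri = 1`.

Other examples: `planted_recovery.py` (exact +100 recovery of planted query
copies in a 10,000-vertex random network), `split_large_query.py` (query
decomposition and the split/plain equivalence), `held_out_study.py` (hiding
20 % of binding edges and rediscovering them by rank).

## Command line

The same pipeline is exposed as a thin CLI:

```sh
semmine simulate spec.json --out random.graphml          # random typed graph
semmine derive graph.graphml known_pairs.tsv             # queries from shortest paths
semmine mine graph.graphml queries/ --st 0.8 --mode per-element
semmine rank inferences.tsv reference.tsv --graph graph.graphml
semmine oracle small.graphml query.json                  # brute-force verification
```

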