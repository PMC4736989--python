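# Methods

## Graph model

The target network is a directed multigraph. Every vertex and edge carries a
type name from a finite vocabulary; parallel edges and self-loops are
allowed; arbitrary string attributes are carried but never consulted by the
matching algorithm. Degree counts edge multiplicity, and a self-loop
contributes 1 to the in-degree and 1 to the out-degree (2 to the total):
the candidate rule `deg_G(v) ≥ deg_Q(r)` must never under-count the edges a
vertex can supply. Identifiers and type names are compared byte-wise,
case-sensitively. Graphs round-trip through GraphML (a mandatory `type` data
key on nodes and edges; other data keys become attributes) and through a
TSV node/edge dialect.

A query is a small connected typed digraph (connectivity checked on the
undirected view, at least 2 roles). Its optional inference annotation
`(drug role, target role, edge type)` names the relation read off each
mapping; the annotated edge type need not occur among the structural edges.

## Semantic distance and thresholding

The semantic distance calculator is a pair of square symmetric matrices with
unit diagonal and entries in [−1, 1], one over vertex types and one over
edge types. The anchor values are 1 for semantically identical types, 0 for
unrelated, −1 for opposite; entries are deliberately graded reals rather
than the bare three values, so users can encode hierarchy-derived similarity
between near-synonymous types. A type pair absent from a matrix scores 0
("unrelated"), which lets a network with extra types be mined without matrix
edits; an unknown type scores 1 against itself.

The semantic score of a complete mapping is the arithmetic mean over all
`|V(Q)| + |E(Q)|` elements — vertex and edge elements are scored alike and
share one denominator. The threshold `ST ∈ [0, 1]` (default 0.8) is applied
with `≥` in one of two modes: *per element* (every element passes) or
*cumulative* (the mean passes). Per-element acceptance implies cumulative
acceptance at the same threshold. Threshold comparisons carry an absolute
slack of 1e-9 so exact boundary cases (a mean of 4/5 against 0.8) are not
lost to floating-point rounding.

## Search

The matcher is a depth-first backtracking search in the VF tradition:

- **Anchor.** The search roots at the query role of the configured anchor
  type (default `Compound`) with maximum degree, ties broken by smallest
  role id; if the query has no role of that type the globally
  maximum-degree role is used and a warning issued. Initial candidates are
  the target vertices whose type passes the semantic test against the anchor
  role and whose total degree is at least the anchor's.
- **Extension order.** The next role is always adjacent to the mapped set,
  most-constrained (highest degree) first; its candidates are drawn from the
  neighbors of an already-mapped image, never the whole graph.
- **Closed world, incrementally.** On assigning a vertex, the directed edge
  counts between it and every already-mapped image must *equal* the query's
  counts (including zero counts and self-loops). This enforces the induced-
  match semantics during the search rather than as a post-filter. The
  printed degree-equivalence variant of the rule (mapped vertices must have
  exactly the query role's total degree) would contradict the candidate rule
  `deg_G ≥ deg_Q`; it is nevertheless exposed as an opt-in `strict_degree`
  mode, off by default.
- **Edge assignment.** With all roles assigned, query edges are matched to
  distinct target edges group-by-group per ordered role pair; parallel query
  edges enumerate permutations of the parallel target edges. Each distinct
  (vertex assignment, edge assignment) pair is one mapping — automorphic
  re-embeddings onto the same vertex set count separately (raw-count
  semantics, which is what makes the planted-copy arithmetic exact for rigid
  queries); a `dedup_orbits` flag collapses them on request.
- **Cumulative-mode pruning.** A branch is abandoned only when provably
  hopeless: `partial_sum + (elements_remaining × 1) < ST × n`.

`brute_force_search` is the testing oracle: it enumerates injective role
assignments over all vertices in a fixed breadth-first role order with no
anchor, no candidate sets and no incremental closed-world bookkeeping
(prefixes are abandoned only when an already-violated query edge can never
be repaired, which does not change the accepted set), then post-filters with
independently written closed-world, threshold and edge-assignment checks.
It refuses graphs beyond 60 vertices. A further cross-check in the tests
compares vertex assignments against networkx's node-induced subgraph
isomorphism on multigraphs at full semantic identity.

## Pruning

Before a search, target vertices whose types are distant from every query
vertex type can be removed with their incident edges, and any vertex left
isolated (or isolated to begin with) removed afterwards. A type survives iff
its *maximum* score against the query's vertex types reaches the threshold —
the aggregation is a deliberate design choice: a type close to any query
role may participate in a mapping, so anything weaker than max would be
unsafe. Pruning is idempotent and, in per-element mode, provably
result-preserving; in cumulative mode it may discard a below-threshold
element that a high-scoring mapping would have absorbed, so it defaults on
for per-element runs and off for cumulative runs.

## Splitting

Queries with more than 3 roles are recursively decomposed. One round picks
the overlap node ON as the maximum-degree role of the undirected view (ties:
minimum eccentricity, then smallest id — pure degree ties are common in
small queries), then the pair of remaining roles at maximum pairwise
undirected distance (ties: smallest id pair; "most distant" is read as
pairwise distance among the remaining roles, matching the picture of a path
split at its midpoint into its two endpoints' branches). The shortest paths
from those two roles to ON (unit weights, lexicographically smallest role-id
sequence among ties) seed the two parts; every remaining role joins the part
holding more of its already-allocated neighbors (ties: the smaller part,
then the first); an edge belongs to a part iff both endpoints do, and edges
spanning parts become *residual*. Recursion continues until every leaf has
at most 3 roles.

The split search runs the smaller part first, seeded at ON with ON's
candidates constrained by its full-query degree; ON images that yielded
embeddings become the second search's domain. Part searches are deliberately
*non-induced* and, in cumulative mode, threshold-deferred: a target edge
between two part images may be accounted for by the other part or by a
residual edge, and a part's mean says nothing about the full mean (an
admissible bound using the full element count is applied instead). Partial
mappings agreeing on all shared roles and injective elsewhere are joined;
residual edge counts are verified; then the closed-world check, the edge
assignment and the threshold are re-established on the joined mapping and
the semantic score recomputed from scratch. This re-checking is what makes
the split route return exactly the plain search's mapping set, which the
test suite asserts on random instances up to 9-role queries and the
acceptance suite on 10,000-vertex graphs.

## Query derivation and deduplication

Given externally known drug–target pairs, the *relevant* subset keeps pairs
whose drug and target both exist in the network but are not joined by an
interaction edge in either direction. For each relevant pair a single
minimum-hop path in the undirected view is computed (unit edge weights;
deterministic lexicographically-smallest tie-breaking; for parallel edges
the smallest edge id is reported with its stored direction). The path
becomes a type-level query — one fresh role per path vertex, identities not
pinned — with the inference annotation from first to last role. Queries are
grouped by typed-digraph isomorphism including the inference annotation;
canonical forms are computed by exhaustive type-partitioned permutation,
which is feasible because derived queries are capped at 9 roles (larger ones
are discarded with a warning). Exact isomorphism (not type-multiset
equality) defines the classes, so triads differing only in edge direction
stay distinct.

## Scoring and ranking

`R_q` divides the known fraction by the query's *unique* inferred pairs (a
query inferring the same pair through many mappings counts it once); a query
with no inferences scores 0 by convention. `R_i` sums `R_q` over supporting
queries, so it is bounded by the total of all query scores. Ranking is
descending `R_i`, ties by descending supporter count, then drug id, then
target id (the tie rule is an artifact decision; nothing in the method
constrains it). Pairs already present as interaction edges are filtered from
the ranked output — the closed-world rule already prevents them, so the
filter is belt-and-braces.

## Synthetic data

Random target networks are generated from a type-level spec: exact per-type
vertex counts and, for each (source type, edge type, target type) triple, an
exact edge count with endpoints uniform over the type populations
(self-loops resampled, parallel edges kept). Per-type average in- and
out-degrees are thereby matched by construction; degree *sequences* are not
controlled (no configuration model), and the generated networks lack the
heavy-tailed hubs, attribute structure and cross-type correlations of real
integrated datasets — passing tests demonstrate algorithmic correctness on
this substrate, not predictive performance on real networks.

Random queries are a uniform random spanning tree plus a chosen number of
extra edges between not-yet-adjacent role pairs; avoiding duplicate pairs
keeps a distinct-typed query free of parallel edges, hence exactly one
mapping per planted copy. Planted instances are vertex-disjoint fresh
components with exactly the query's edges; connecting them to the bulk could
create mixed mappings and break the +k arithmetic. The default study sizes
(10,000-vertex networks, 100 planted copies, 50 random 6-role queries,
25-seed equivalence sweeps) were chosen as the package's standard evaluation
conditions and run in minutes on one CPU.

The held-out study builds a network of compound clusters (pairwise
similar compounds sharing 2 targets each, 25 clusters of 3 compounds by
default) plus unstructured noise compounds/targets with random similarity
and binding edges. 20 % of binding edges are hidden; queries are derived
from the shortest paths between the hidden pairs on the censored network and
scored against those same pairs, mirroring the intended use where a newer
knowledge release both motivates and scores the query set. The check is
relative (median rank of hidden pairs vs an equal-sized random sample of
never-true inferences), not an absolute recovery rate.

## Numerical and degenerate-input choices

- Tie-breaking is deterministic everywhere (lexicographic ids); repeated
  runs with the same seed are bitwise reproducible.
- 0/0 conventions: `R_q = 0` for inference-free queries; an empty mapping
  list is a valid search result, not an error.
- Disconnected queries, queries with fewer than 2 roles, dangling edge
  endpoints, asymmetric or out-of-range distance matrices are rejected with
  specific exceptions at construction/load time.
- `max_mappings` truncates the enumeration deterministically; it is ignored
  inside part searches (a cap there could starve valid joins).

## Known limitations

- The matcher is pure Python; exhaustive searches on networks beyond ~10^5
  vertices or on match-rich queries (hundreds of thousands of mappings) are
  memory- and time-bound. The split route's join overhead grows with the
  number of partial matches, so its advantage shows on sparse-match
  instances.
- Semantic scoring is type-level only; attributes and provenance do not
  contribute to scores.
- Distance matrices must be supplied (or identity matrices generated); no
  ontology-derived similarity is computed.
- Inexact topological matching (edit distances, missing-edge tolerance) is
  out of scope; matches are topologically exact by design.
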