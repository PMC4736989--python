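"""The guilt-by-association worked example.

Chlorpromazine binds three annotated targets, none explaining its known
antihistaminic effect; it is structurally similar to trimeprazine, which
binds the Histamine H1 receptor.  Mining the network with the triad query
(compound similar to a compound that binds a target) recovers exactly that
repositioning inference.
"""

import semmine as sm

G, Q = sm.chlorpromazine_fixture()
M = sm.identity_sdc(G.vertex_type_vocabulary, G.edge_type_vocabulary)

mappings = sm.mine_query(G, Q, M, sm.SearchConfig(st=0.8, mode="per_element"))
print(f"graph: |V|={G.num_vertices()}, |E|={G.num_edges()}")
print(f"mappings found: {len(mappings)}")
for m in mappings:
    print(f"  roles -> vertices: {m.vertex_assignment}   SS={m.ss}")

inferred = sm.mappings_to_inferences(mappings, Q)
print(f"inferred interaction: {inferred[0]}")

# score the query against a reference that contains the known repositioning
ref = sm.ReferenceInteractionSet({("chlorpromazine", "Histamine H1 receptor")})
score = sm.score_query(inferred, ref, Q.name)
ranked = sm.rank_interactions(sm.score_interactions({Q.name: inferred}, [score]))
print(f"query recovery score Rq = {score.rq}")
print(f"top-ranked interaction: {ranked[0].drug} -> {ranked[0].target} "
      f"(Ri = {ranked[0].ri})")
# Rq = 1 means every unique inference of this query is a known interaction;
# Ri sums Rq over all queries supporting the pair (here just one).
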