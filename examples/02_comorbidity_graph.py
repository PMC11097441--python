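"""Mine trigger->target comorbidities and build the weighted disease graph.

A disease is a comorbidity of a trigger when it appears after the trigger's
k-th occurrence in a patient's flattened sequence. Trigger diseases and
their targets become graph vertices; edge weights compare the two
endpoints' frequency-ranked comorbidity lists (smaller = more similar),
each common comorbidity weighted by its cross-patient entropy.
"""

from emrbert import build_graph, embed_graph, find_comorbidities, \
    select_triggers
from emrbert.synthetic import (CohortConfig, default_noise_codes,
                               generate_cohort, worked_example)

# the printed worked example: with trigger 250.0 and k=2, hypertension
# (401.9) appears after the second occurrence of 250.0
support = find_comorbidities([worked_example()], trigger="250.0", k=2)
print("comorbidities of 250.0 (k=2):", sorted(support))

# on a synthetic cohort, select triggers (>2 occurrences in one patient,
# has comorbidities, not noise, >=1% prevalence) and build the graph
records, _ = generate_cohort(CohortConfig(n_patients=150), seed=0)
triggers = select_triggers(records, noise=default_noise_codes(), k=2)
graph = build_graph(records, triggers, noise=default_noise_codes())
print(f"graph: {len(graph.vertices)} diseases, {len(graph.edges)} edges")

w = sorted(((graph.weight(u, v), u, v) for u, v in graph.graph.edges))
print("three closest disease pairs (lowest rank-distance weight):")
for weight, u, v in w[:3]:
    print(f"  {u} -- {v}: {weight:.3f}")

emb = embed_graph(graph, d_emb=64, seed=0)
print(f"embedded {len(emb.vocab)} diseases into",
      f"{emb.vectors.shape[1]}-dimensional vectors")
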