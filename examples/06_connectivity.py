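"""Connectivity scoring: find reference perturbations that reverse the query."""

from causalsig import (
    SimulationConfig,
    build_query,
    connectivity_score,
    generate_deg_table,
    generate_network,
    generate_reference_db,
)

cfg = SimulationConfig(seed=1)
net = generate_network(cfg)
table, truth = generate_deg_table(net, cfg)
refdb = generate_reference_db(table, cfg, truth)

query = build_query(table, n_per_side=50)
results = connectivity_score(query, refdb)
print(f"query: {len(query.up)} up / {len(query.down)} down genes")
for r in results[:3]:
    print(f"  {r.signature_id:10s} score {r.score:8.2f}  {r.description}")
print(f"  {results[-1].signature_id:10s} score {results[-1].score:8.2f}  "
      f"{results[-1].description}")
# Scores are normalized to [-100, 100]; -100 marks the strongest
# reverser (a perturbation inverting the query's expression pattern),
# +100 the strongest mimic.
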