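"""Generate a synthetic study: signed network, DEG table, pathways,
biomarkers and a reference signature database, all from one seed."""

from causalsig import (
    SimulationConfig,
    generate_deg_table,
    generate_genesets,
    generate_network,
    generate_reference_db,
)

cfg = SimulationConfig(seed=1)
net = generate_network(cfg)
table, truth = generate_deg_table(net, cfg)
db, tops = generate_genesets(net, truth, cfg)
refdb = generate_reference_db(table, cfg, truth)

print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
print(f"DEG table: {len(table)} genes, {len(truth.true_signal_genes)} signal")
print(f"planted regulators (node, activity sign): {truth.planted_regulators}")
print(f"pathways: {len(db.sets)}; reference signatures: "
      f"{len(refdb.signature_ids)} (incl. {truth.reverser_signature_id})")
# The planted regulators are the ground truth every downstream stage of
# the pipeline should rediscover from the DEG table alone.
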