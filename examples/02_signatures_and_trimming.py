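"""Threshold a DEG table into tiered gene signatures and trim the larger
one down to a causal-engine-sized query list."""

from causalsig import (
    SimulationConfig,
    build_signature,
    generate_deg_table,
    generate_network,
    trim_signature,
)

cfg = SimulationConfig(seed=1)
net = generate_network(cfg)
table, _truth = generate_deg_table(net, cfg)

gs1 = build_signature(table, log2fc_cut=2.00, fdr_cut=0.05, name="GS1")
gs2 = build_signature(table, log2fc_cut=5.00, fdr_cut=0.05, name="GS2")
print(f"GS1 (|log2FC|>=2, FDR<=0.05): {len(gs1.up)} up, {len(gs1.down)} down")
print(f"GS2 (|log2FC|>=5, FDR<=0.05): {len(gs2.up)} up, {len(gs2.down)} down")
print(f"GS2 nested in GS1: {gs2.genes() <= gs1.genes()}")

trimmed = trim_signature(gs1, table, target_n=40)
print(f"GS1 trimmed to <=40 genes: {len(trimmed)} kept, "
      f"|log2FC| cut raised from {gs1.log2fc_cut:.2f} to {trimmed.log2fc_cut:.2f}")
# Trimming raises the symmetric fold-change cut in 0.01 steps, so the
# retained genes are exactly the strongest responders.
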