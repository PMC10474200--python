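"""Score upstream-regulator hypotheses on the signed network and filter
to direct-acting transcription factors."""

from causalsig import (
    SimulationConfig,
    build_signature,
    filter_hypotheses,
    generate_deg_table,
    generate_network,
    intersect_hypotheses,
    score_hypotheses,
)

cfg = SimulationConfig(seed=1)
net = generate_network(cfg)
table, truth = generate_deg_table(net, cfg)
gs1 = build_signature(table, 2.00, 0.05, "GS1")
gs2 = build_signature(table, 5.00, 0.05, "GS2")

hyps1 = score_hypotheses(net, gs1, max_distance=3, alpha=0.05)
hyps2 = score_hypotheses(net, gs2, max_distance=3, alpha=0.05)
print(f"hypotheses at p<=0.05: {len(hyps1)} (GS1), {len(hyps2)} (GS2)")
top = hyps1[0]
print(f"top GS1 hypothesis: {top.node}{top.activity_label} "
      f"{top.k_correct}/{top.n_scored} correct, p={top.p_value:.2e}")

common = intersect_hypotheses(hyps1, hyps2)
print(f"(node, sign) pairs shared by both signatures: "
      f"{[(n, '+' if s > 0 else '-') for n, s, *_ in common[:5]]}")
print(f"planted ground truth: {truth.planted_regulators}")

tf_direct = filter_hypotheses(net, gs1, function="TF", distance=1)
print(f"direct-acting TFs (distance 1, transcription edges): "
      f"{[h.node for h in tf_direct]}")
# A hypothesis is a (regulator, activity sign); p is the upper-tail
# Binomial(n, 1/2) probability of explaining k of n DEG signs by chance.
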