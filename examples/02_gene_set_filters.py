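"""Build the three inference gene sets: enriched+MSE, MSE-only, TFs.

Runs the endosperm-enrichment classifier on simulated counts (log2FC > 1.5,
FDR < 0.01), the Modified Shannon Entropy filter on time-point means
(outlier score < 30%), and identifier-based TF selection.
"""

from seedgrn import (
    attach_fdr,
    classify_enriched,
    differential_enrichment,
    mse_filter,
    sample_ground_truth_network,
    select_tfs,
    simulate_time_course,
    simulate_two_condition_counts,
)

counts = simulate_two_condition_counts(2000, 200, 2.0, 0.1, 7, seed=3)
records = attach_fdr(differential_enrichment(counts))
enriched = classify_enriched(records)  # log2FC > 1.5 and FDR-adjusted p < 0.01
truth = set(counts.truth[counts.truth].index)
tp = len(enriched & truth)
print(f"enriched: {len(enriched)} of 2000 genes "
      f"(sensitivity {tp / len(truth):.2f}, "
      f"false positives {len(enriched - truth)})")

net = sample_ground_truth_network(200, 40, 2, 0.3, seed=1)
expr = simulate_time_course(net, seed=2)
dynamic = mse_filter(expr.time_point_means())
print(f"MSE filter: {len(dynamic)} of {len(net.genes)} genes show at least one "
      "low-entropy (outlier) time point")

annotations = {g: ({"GO:0003700"} if g in net.regulators else {"PF00000"})
               for g in net.genes}
tfs = select_tfs(annotations, {"GO:0003700", "GO:0003677"})
print(f"TF selection: {len(tfs)} genes annotated with TF identifiers")
# Each printed set is the input to one pair of inferred networks.
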