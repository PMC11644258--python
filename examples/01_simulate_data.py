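"""Generate a synthetic study: ground-truth network, time course, counts.

Builds a 200-gene network with 40 regulators, simulates a 6-time-point
(0-8 DAP) expression course with 3 replicates, and a 7-vs-7 endosperm vs
whole-seed count contrast with 200 truly enriched genes.
"""

from seedgrn import (
    sample_ground_truth_network,
    simulate_time_course,
    simulate_two_condition_counts,
)

net = sample_ground_truth_network(
    n_genes=200, n_regulators=40, avg_out_degree=2, repressor_fraction=0.3, seed=1
)
print(f"ground truth: {len(net.genes)} genes, {len(net.regulators)} regulators, "
      f"{len(net.edges)} signed edges")

expr = simulate_time_course(net, seed=2)
print(f"expression: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples "
      f"({len(expr.time_points)} time points x 3 replicates)")

counts = simulate_two_condition_counts(
    n_genes=2000, n_enriched=200, effect_log2fc=2.0, dispersion=0.1,
    n_reps_per_group=7, seed=3,
)
print(f"counts: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples, "
      f"{int(counts.truth.sum())} genes truly enriched")
# The edge count is binomial around n_regulators * avg_out_degree (~80);
# every downstream stage can be scored against these recorded truths.
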