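"""Motif census, enrichment against a degree-preserving null, and NMS.

Plants 30 disjoint feed-forward loops (A->B, A->C, B->C), tests all 13
connected 3-node motif classes against randomized networks of identical
degree sequences, and scores genes by enriched-motif membership.
"""

from seedgrn.containers import DirectedGRN, GRNEdge
from seedgrn.motifs import FFL, motif_enrichment, nms

edges = []
for i in range(30):
    a, b, c = f"a{i}", f"b{i}", f"c{i}"
    edges += [GRNEdge(a, b), GRNEdge(a, c), GRNEdge(b, c)]
net = DirectedGRN(edges)

enrichment = motif_enrichment(net, n_random=1000, z_threshold=3.0, seed=0)
for e in enrichment:
    if e.count_real or e.enriched:
        print(f"class {e.motif_class}: {e.count_real} instances, "
              f"null {e.mean_random:.1f} +/- {e.sd_random:.1f}, "
              f"Z = {e.z_score:.1f}, enriched = {e.enriched}")

scores = nms(net, enrichment)
print(f"NMS table covers {len(scores)} genes; every loop member scores "
      f"{scores['a0']} (it sits in exactly one enriched instance)")
# The feed-forward loop class (030T) is massively over-represented because
# degree-preserving rewiring destroys the planted loops.
assert [e for e in enrichment if e.motif_class == FFL][0].enriched
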