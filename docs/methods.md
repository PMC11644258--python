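# Methods

`seedgrn` reimplements, as a tested library, a gene-regulatory-network (GRN)
analysis workflow for developmental time-course RNA-seq of seeds: gene-set
construction (endosperm-enrichment classification, entropy filtering,
transcription-factor selection), dual network inference (a tree-ensemble
engine and a kernel-boosting engine), directed 3-node motif enrichment
against a degree-preserving null, per-gene network-motif scoring, and
permutation testing of the edge overlap between inferred networks. Every
stage can be exercised on synthetic data with a known ground truth; this
note records the models, the defaults and why, and what the synthetic
benchmarks do and do not demonstrate.

## Synthetic data model

The generator produces the three objects the analysis consumes.

**Ground-truth network.** `sample_ground_truth_network` draws a sparse
signed bipartite-ish regulator→gene network: each of the
`n_regulators × (n_genes − 1)` loop-free ordered pairs becomes an edge
independently with probability `avg_out_degree / (n_genes − 1)`, so the
edge count is binomial with mean `n_regulators × avg_out_degree`. A
configurable fraction of edges are repressive (sign −1); strengths are
uniform on [0.5, 1.5].

**Time course.** Expression is simulated on the default sampling grid
0/2/4/6/7/8 days after pollination (DAP) with 3 replicates, mirroring a
developmental seed experiment with unfertilized ovules as the 0-DAP
baseline. Regulators — and unregulated genes — follow exogenous
log-Gaussian-process curves (RBF bandwidth = span/5 days, per-gene
amplitude uniform on [0.5, 3]): smooth developmental waves peaking at
different stages rather than one shared trend. Dynamics are propagated on
a fine internal grid (4 steps/day): a regulated gene's value at each step
is `max(0, b + g·z)`, a clipped linear response with per-gene baseline
`b ~ U(1, 2)` and gain `g ~ U(0.8, 1.5)`, where `z` is the standardized
signed strength-weighted sum of its regulators' expression at the previous
internal step. Two consequences are deliberate:

- regulation acts with a ~0.25-day lag, fast relative to the ~2-day
  sampling interval — the regime in which concurrent-sample inference
  (both engines regress targets on same-sample regulator values) is
  well-posed;
- each biological replicate carries its own smooth multiplicative
  deviation from the shared curve (log-scale amplitude `noise_sd`,
  default 0.2) that **propagates** from regulators to targets, plus iid
  measurement noise (sd `noise_sd/2`) that does not. This mirrors
  replicated RNA-seq — biological variation dominates technical noise at
  moderate expression — and it is what makes the inference problem
  identifiable at all: with only six time points, any 40 smooth mean
  curves are mutually correlated enough that some non-regulator matches a
  target's mean profile at |r| > 0.93, so profile shape alone cannot
  single out the true regulator. Shared replicate-level variation is the
  extra, full-rank signal that real data carry and regression-based
  engines exploit.

With `noise_sd = 0` the simulation is deterministic and replicates are
identical. The generator does **not** emulate: read-level sampling,
library-size or length biases, cascades among targets (regulators are
exogenous; a regulator that is itself a target keeps its exogenous curve),
feedback loops, or unmodelled confounders. Passing benchmarks on this data
therefore show that the engines recover regulator→target dependencies of
the assumed form at realistic noise; they do not certify performance on
real seed RNA-seq, where none of the simplifications above hold exactly.

**Two-condition counts.** `simulate_two_condition_counts` draws
negative-binomial counts (variance `m + φm²`, default dispersion φ = 0.1)
around log-normal baseline means (log-mean 4, log-sd 1; median ≈ 55
counts) for two groups of 7 replicates, the endosperm group carrying a
`2^effect_log2fc` mean increase (default log2FC = 2) on exactly
`n_enriched` flagged genes.

## Gene-set filters

**Enrichment classification.** Counts are normalized to CPM using
median-of-ratios effective library sizes (anchored on the geometric mean of
the raw totals). Plain total-count normalization is biased here: the
enriched subset inflates the endosperm libraries and shrinks every apparent
fold change by the same factor — the composition effect that dedicated
count-model tools solve with robust normalization. Log2 fold change is
computed between pseudocounted (0.5) group means of CPM; the raw p-value is
a Welch t-test on log2(CPM+1); FDR adjustment is Benjamini–Hochberg. A gene
is endosperm-enriched iff log2FC > 1.5 (strictly) and adjusted p < 0.01
(strictly). This deliberately lightweight test stands in for a
negative-binomial GLM; the record interface accepts externally computed
(log2FC, p) tables so that output from such a tool can be dropped in.

**Modified Shannon Entropy (MSE) filter.** For a profile of per-time-point
means `m_t`, let `p_t = m_t / Σm`. Each value scores
`e_t = −p_t·log2(p_t)` (with 0·log2 0 = 0), normalized by the maximum
attainable point entropy `log2(e)/e ≈ 0.5307` so the score is scale-free.
A value scoring below 0.30 is an outlier — either a dominating spike or a
near-vanishing dip — and a gene is retained iff it has at least one outlier
time point; all-zero profiles are excluded. The cited entropy-filtering
literature does not print a unique formula; this normalization is one
defensible reading, chosen so that "30%" refers to a fixed [0, 1] scale.
Whether to compute entropy on time-point means or per-replicate values was
open; means are used, consistent with their role everywhere else in the
pipeline.

**TF selection** is exact identifier-set intersection (GO/InterPro/PFam/
PANTHER); intersecting with an expressed-gene set is the caller's choice.

## Tree-ensemble engine

For each target gene a `RandomForestRegressor` (default 300 trees;
importance estimates stabilize well below the 1000 commonly used, at these
sample counts) predicts the target's expression across all samples from
all candidate regulators except itself; the per-target importances
(impurity reduction) are normalized to sum to one. Trees consider every
candidate at each split (`max_features = 1.0`); bootstrap resampling alone
randomizes the ensemble. With the GENIE3-style `sqrt` feature subsampling,
irrelevant regulators accrue importance through forced splits — at two
candidates an irrelevant feature captured ~19% — whereas full-feature
splits leave it near zero while edge-ranking quality at scale is equal or
better.

Per iteration, edges above the `(1 − top_fraction)` quantile of all
off-diagonal importances are kept (ties at the cutoff included,
zero-importance pairs never). Default `top_fraction = 0.05`: at the
default synthetic scale this yields a consensus network with roughly twice
as many edges as the one-edge-per-target posterior-argmax network, the
edge-density regime reported when both engine families are run on the same
gene set; a much smaller fraction would invert the observed topology
contrast. Five iterations (differing only in forest seed) are combined by
majority consensus (`⌈k/2⌉`); runs on large gene sets conventionally use a
single iteration, in which case consensus is the identity.

Each surviving edge is signed by the Pearson correlation `r` of the source
and target time-point mean profiles: promoting if `r > τ`, repressing if
`r < −τ`, otherwise (or for zero-variance profiles) just "regulating".
Default dead zone τ = 0.3; the three-way labelling is the convention of
the upstream pipeline this engine reimplements, which does not publish its
exact rule — τ is therefore configuration-exposed.

## Kernel-boosting engine

For each target, candidates are scored by regression on kernel
principal-component features of their own expression vector: the RBF Gram
matrix over samples is double-centered and the top eigenvectors, scaled by
root-eigenvalue, form the feature block. Defaults: 3 components and
bandwidth 2× the median pairwise distance. Both were chosen at design
time against the synthetic benchmark: 5 components, or a 1× bandwidth,
make the per-candidate least-squares fits flexible enough to chase
spuriously correlated candidates at ~18 samples (argmax recovery collapsed
from ~0.94 to ~0.4), while 3 smooth components track the identifiability
ceiling of the data.

Boosting runs 3 rounds with shrinkage 0.5: each round fits every candidate
to the current residual, converts residual sums of squares to weights by
BIC-weighted Bayesian model averaging under a uniform prior
(`w ∝ exp(−ΔBIC/2)`, no prior edge weights), accumulates the weights, and
adds the shrunken best fit to the running prediction. The accumulated
weights, divided by the number of rounds, are the posterior column for the
target (sums to 1 by construction; a single-candidate target gets
posterior 1). The procedure is deterministic and ignores the time ordering
of samples entirely — by design, matching how this engine family is run on
time-course data. Edges are the per-target posterior argmax, ties
included, unsigned; a top-k relaxation is available via the posterior
matrix itself.

## Motif census and enrichment

A motif class is an isomorphism class of weakly connected loop-free
3-node digraphs; there are exactly 13, named by the standard triad-census
labels (030T is the feed-forward loop). Canonicalization minimizes the
6-bit adjacency string over the 6 node permutations; the census enumerates
connected triples from edge neighborhoods (each triple counted once) and
stores instances in role-consistent (canonical) node order. Signs and
weights are ignored; reciprocal edge pairs are allowed and distinguish
classes.

The null model is degree-preserving switching that **also preserves the
number of reciprocal dyads** (single arcs swap with single arcs, rejecting
swaps that would create a mutual pair; mutual dyads swap with mutual
dyads), the standard null for directed motif detection. Without
reciprocity preservation, classes containing mutual edges come out
spuriously enriched in otherwise null networks, because plain switching
destroys reciprocity and essentially never rebuilds it. Each of the
default 1000 randomized copies uses `swap_factor × |E|` attempted swaps
per group (default 10). An Erdős–Rényi same-size null is available behind
a flag. Enrichment: `z = (real − mean)/sd` over the ensemble, enriched iff
`z > 3.0`; a class with zero ensemble variance reports z = 0 and is never
enriched. Known limitation: for classes whose counts are tiny integers
(0–2), the z statistic is a rare-event score and exceeds 3.0 in a few
percent of genuinely null networks; calibration experiments should use
networks whose occupied classes have non-trivial counts.

The network motif score (NMS) of a gene is the number of enriched-class
instances containing it; genes in no enriched instance are absent from the
table.

## Overlap permutation test

The observed overlap is the number of directed edges shared by networks A
and B (an undirected mode collapses orientation). Each of the default
10,000 permutations draws `|E_A|` gene pairs — two distinct genes per
pair, no pair repeated within a permutation — uniformly from the common
gene universe and counts hits on B's edge set; the p-value is
`(1 + #{permuted ≥ observed})/(1 + n)`, never zero by construction. "Pair
without replacement" admitted two readings (within-pair and across-pair
distinctness); both are enforced, and both the direction convention and
the choice that A supplies the pair count are configuration-exposed. The
null overlap mean has the closed form `|E_A||E_B| / (U(U−1))` over a
universe of size U, used as a cross-check in the tests. Because the
overlap is integer-valued, the empirical p-value is slightly conservative
and discrete; calibration against the uniform distribution is meaningful
only when the null overlap spans many integers.

## Pipeline and I/O

`run_pipeline` binds the stages in the published workflow shape: build one
of the three gene sets (enriched+MSE, MSE-only, TF), infer with one or
both engines on the expression of that set, census and enrich motifs,
score genes, and — when both engines ran — test their overlap. All files
are tab-separated with `#`-prefixed provenance headers (package version,
seed, parameters); SIF output is provided for network viewers. All
randomness descends from the single config seed, and a rerun with an
identical config is byte-identical.

## Benchmark problem sizes

The bundled tests and the reproduction script run the synthetic study at
200 genes / 40 regulators / ~80 true edges / 6 time points × 3 replicates
(inference), 2000 genes with 200 enriched / 7 vs 7 replicates (enrichment),
50 planted feed-forward loops vs 1000 randomized networks (motifs), and
10,000 resamples (overlap) — sizes chosen so the full suite completes on a
single CPU in minutes while every statistic retains enough resolution for
its acceptance band.
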