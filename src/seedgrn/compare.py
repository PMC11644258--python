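"""Edge-overlap quantification and permutation testing between two networks.

The null model mirrors the gene-pair resampling scheme used to compare the
two inference engines: each permutation draws as many distinct ordered gene
pairs as the first network has edges, uniformly from the shared gene
universe, and counts how many land on edges of the second network. The
empirical p-value uses add-one smoothing so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DirectedGRN

DEFAULT_N_PERMUTATIONS = 10_000


def edge_overlap(a: DirectedGRN, b: DirectedGRN, directed: bool = True) -> int:
    """Number of edges present in both networks.

    With ``directed=False`` an edge matches regardless of orientation.
    """
    ea = a.edge_pair_set()
    eb = b.edge_pair_set()
    if directed:
        return len(ea & eb)
    ua = {frozenset(p) for p in ea}
    ub = {frozenset(p) for p in eb}
    return len(ua & ub)


def _sample_distinct(rng: np.random.Generator, n_possible: int, size: int) -> np.ndarray:
    """Uniform sample of ``size`` distinct integers from range(n_possible).

    Rejection sampling: fast when size << n_possible, falls back to a full
    permutation when the sample covers most of the range.
    """
    if size * 2 >= n_possible:
        return rng.permutation(n_possible)[:size]
    chosen = np.unique(rng.integers(0, n_possible, size=size))
    while chosen.size < size:
        extra = rng.integers(0, n_possible, size=size - chosen.size)
        chosen = np.unique(np.concatenate([chosen, extra]))
    return chosen


@dataclass
class OverlapResult:
    """Observed overlap between two networks and its permutation null."""

    observed_overlap: int
    overlap_fraction: float  # observed / |E_A|
    n_permutations: int
    perm_mean: float
    perm_sd: float
    perm_max: int
    p_value: float


def overlap_permutation_test(
    a: DirectedGRN,
    b: DirectedGRN,
    gene_universe: set[str] | list[str],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    directed: bool = True,
    seed: int = 0,
) -> OverlapResult:
    """Gene-pair resampling test of the overlap between networks a and b.

    Each permutation samples ``|E_A|`` gene pairs without replacement — the
    two genes within a pair are distinct, and no pair repeats within one
    permutation — from ``gene_universe``, and records how many coincide with
    edges of ``b``. ``p = (1 + #{permuted >= observed}) / (1 + n)``.
    """
    universe = sorted(set(gene_universe))
    u = len(universe)
    if u < 3:
        raise ValueError("gene universe must contain at least 3 genes")
    endpoints = {n for e in a.edges for n in (e.source, e.target)} | {
        n for e in b.edges for n in (e.source, e.target)
    }
    stray = endpoints - set(universe)
    if stray:
        raise ValueError(f"edge endpoints outside the gene universe: {sorted(stray)[:5]}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")

    n_pairs = len(a.edges)
    n_possible = u * (u - 1)
    if n_pairs > n_possible:
        raise ValueError("more edges in A than distinct ordered gene pairs")

    observed = edge_overlap(a, b, directed=directed)

    # encode ordered pairs as integers i*(u-1) + j' with the diagonal removed
    pos = {g: i for i, g in enumerate(universe)}

    def pair_code(s: str, t: str) -> int:
        i, j = pos[s], pos[t]
        return i * (u - 1) + j - (j > i)

    if directed:
        b_codes = np.fromiter(
            (pair_code(s, t) for s, t in b.edge_pair_set()), dtype=np.int64
        )
    else:
        both = set()
        for s, t in b.edge_pair_set():
            both.add((s, t))
            both.add((t, s))
        b_codes = np.fromiter((pair_code(s, t) for s, t in both), dtype=np.int64)
    b_codes = np.unique(b_codes)

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations, dtype=np.int64)
    for k in range(n_permutations):
        draw = _sample_distinct(rng, n_possible, n_pairs)
        permuted[k] = np.isin(draw, b_codes, assume_unique=True).sum()

    p = (1 + int((permuted >= observed).sum())) / (1 + n_permutations)
    return OverlapResult(
        observed_overlap=observed,
        overlap_fraction=observed / n_pairs if n_pairs else 0.0,
        n_permutations=n_permutations,
        perm_mean=float(permuted.mean()),
        perm_sd=float(permuted.std(ddof=1)) if n_permutations > 1 else 0.0,
        perm_max=int(permuted.max()),
        p_value=p,
    )


@dataclass
class TopologySummary:
    """Size and degree statistics of one network."""

    n_nodes: int
    n_edges: int
    mean_in_degree: float
    max_in_degree: int
    mean_out_degree: float
    max_out_degree: int
    in_degree_histogram: dict[int, int]


def topology_summary(net: DirectedGRN) -> TopologySummary:
    """Node/edge counts and in/out-degree statistics over the node set."""
    nodes = sorted(net.nodes)
    indeg = {n: 0 for n in nodes}
    outdeg = {n: 0 for n in nodes}
    for e in net.edges:
        outdeg[e.source] += 1
        indeg[e.target] += 1
    n = len(nodes)
    in_vals = list(indeg.values())
    out_vals = list(outdeg.values())
    hist: dict[int, int] = {}
    for d in in_vals:
        hist[d] = hist.get(d, 0) + 1
    return TopologySummary(
        n_nodes=n,
        n_edges=len(net.edges),
        mean_in_degree=sum(in_vals) / n if n else 0.0,
        max_in_degree=max(in_vals, default=0),
        mean_out_degree=sum(out_vals) / n if n else 0.0,
        max_out_degree=max(out_vals, default=0),
        in_degree_histogram=hist,
    )
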