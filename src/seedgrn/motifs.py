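"""Three-node network-motif census, randomization null, enrichment and scoring.

A motif class is an isomorphism class of weakly connected, loop-free
directed graphs on three nodes; there are exactly 13 of them, named here by
the standard triad-census labels (021D, 021U, 021C, 111D, 111U, 030T, 030C,
201, 120D, 120U, 120C, 210, 300 — e.g. 030T is the feed-forward loop and
030C the three-cycle). Over-representation is tested against an ensemble of
degree-preserving randomized copies of the network: a class is enriched
when its count in the real network exceeds the randomized mean by more than
``z_threshold`` standard deviations. Per-gene network motif scores (NMS)
count how many enriched-class instances contain each gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .containers import DirectedGRN, GRNEdge

#: feed-forward loop triad label (A->B, A->C, B->C)
FFL = "030T"

Z_THRESHOLD = 3.0
DEFAULT_N_RANDOM = 1000
DEFAULT_SWAP_FACTOR = 10

# bit positions of the six possible directed arcs among local nodes 0,1,2
_ARCS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_ARC_BIT = {arc: i for i, arc in enumerate(_ARCS)}


def _code_from_arcs(arcs: set[tuple[int, int]]) -> int:
    code = 0
    for arc in arcs:
        code |= 1 << _ARC_BIT[arc]
    return code


def _arcs_from_code(code: int) -> set[tuple[int, int]]:
    return {arc for arc, bit in _ARC_BIT.items() if code & (1 << bit)}


def _is_weakly_connected(arcs: set[tuple[int, int]]) -> bool:
    und = {0: set(), 1: set(), 2: set()}
    for a, b in arcs:
        und[a].add(b)
        und[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        for nb in und[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == 3


def _build_tables() -> tuple[dict[int, int | None], dict[int, tuple[int, ...]], dict[int, str]]:
    """Canonicalization tables over all 64 loop-free 3-node digraphs.

    Returns (code -> canonical code or None if disconnected,
    code -> permutation of local nodes achieving the canonical code,
    canonical code -> triad-census name).
    """
    canon: dict[int, int | None] = {}
    canon_perm: dict[int, tuple[int, ...]] = {}
    for code in range(64):
        arcs = _arcs_from_code(code)
        if not _is_weakly_connected(arcs):
            canon[code] = None
            continue
        best, best_perm = None, None
        for perm in permutations(range(3)):
            recoded = _code_from_arcs({(perm[a], perm[b]) for a, b in arcs})
            if best is None or recoded < best:
                best, best_perm = recoded, perm
        canon[code] = best
        canon_perm[code] = best_perm

    # name each canonical form with the standard triad-census label,
    # taken from networkx's triad definitions so labels match the convention
    import networkx as nx

    names: dict[int, str] = {}
    local = {"a": 0, "b": 1, "c": 2}
    for name in (
        "021D", "021U", "021C", "111D", "111U", "030T", "030C",
        "201", "120D", "120U", "120C", "210", "300",
    ):
        g = nx.triad_graph(name)
        code = _code_from_arcs({(local[u], local[v]) for u, v in g.edges()})
        names[canon[code]] = name  # type: ignore[index]
    return canon, canon_perm, names


_CANON, _CANON_PERM, _CLASS_NAME = _build_tables()
#: the 13 connected 3-node directed classes, in canonical-code order
MOTIF_CLASSES: tuple[str, ...] = tuple(
    _CLASS_NAME[c] for c in sorted(set(_CLASS_NAME))
)


def canonical_class(arcs: set[tuple[int, int]] | list[tuple[int, int]]) -> str | None:
    """Motif class of a 3-labeled-node arc set, or None if not weakly connected.

    Nodes must be labeled 0, 1, 2; self-loops are rejected.
    """
    arcs = set(arcs)
    for a, b in arcs:
        if a == b:
            raise ValueError("self-loops are not allowed")
        if not {a, b} <= {0, 1, 2}:
            raise ValueError("nodes must be labeled 0, 1, 2")
    code = _code_from_arcs(arcs)
    canon = _CANON[code]
    return None if canon is None else _CLASS_NAME[canon]


def _adjacency(net: DirectedGRN) -> tuple[set[tuple[str, str]], dict[str, set[str]]]:
    pairs = net.edge_pair_set()
    und: dict[str, set[str]] = {n: set() for n in net.nodes}
    for s, t in pairs:
        und[s].add(t)
        und[t].add(s)
    return pairs, und


def _connected_triples(
    pairs: set[tuple[str, str]], und: dict[str, set[str]]
) -> set[tuple[str, str, str]]:
    triples: set[tuple[str, str, str]] = set()
    for s, t in pairs:
        for w in und[s] | und[t]:
            if w != s and w != t:
                triples.add(tuple(sorted((s, t, w))))
    return triples


def census(net: DirectedGRN, with_instances: bool = True) -> dict[str, tuple[int, list[tuple[str, str, str]]]]:
    """Count every weakly connected node triple once under its motif class.

    Returns a mapping from each of the 13 class names to (count, instances);
    an instance is the node triple reordered so that node roles match the
    canonical form of its class. With ``with_instances=False`` the instance
    lists are left empty (fast path for the randomization ensemble).
    """
    pairs, und = _adjacency(net)
    result: dict[str, tuple[int, list[tuple[str, str, str]]]] = {
        name: (0, []) for name in MOTIF_CLASSES
    }
    for triple in _connected_triples(pairs, und):
        local_arcs = {
            (i, j)
            for i, a in enumerate(triple)
            for j, b in enumerate(triple)
            if i != j and (a, b) in pairs
        }
        code = _code_from_arcs(local_arcs)
        canon = _CANON[code]
        name = _CLASS_NAME[canon]  # connected by construction
        count, instances = result[name]
        if with_instances:
            perm = _CANON_PERM[code]
            ordered = [None, None, None]
            for local, node in enumerate(triple):
                ordered[perm[local]] = node
            instances.append(tuple(ordered))
        result[name] = (count + 1, instances)
    return result


def randomize(net: DirectedGRN, swap_factor: int = DEFAULT_SWAP_FACTOR, seed: int = 0) -> DirectedGRN:
    """Degree-preserving switching randomization of a directed network.

    Edge swaps (a->b, c->d) -> (a->d, c->b) preserve every node's in- and
    out-degree exactly. As is standard for directed motif detection, the
    number of reciprocal (mutual) dyads is preserved as well: single arcs
    swap only with single arcs (rejecting swaps that would create or
    destroy a mutual pair) and mutual dyads swap with mutual dyads, so that
    classes containing reciprocal edges are not spuriously enriched merely
    because plain switching cannot regenerate reciprocity. ``swap_factor *
    |E|`` swaps are attempted per group; swaps creating self-loops or
    duplicate edges are rejected. Weights and signs are dropped
    (structure-only null model).
    """
    if len(net.edges) < 2:
        raise ValueError("need at least 2 edges to randomize")
    rng = np.random.default_rng(seed)
    all_pairs = [(e.source, e.target) for e in net.edges]
    present = set(all_pairs)

    singles = [p for p in all_pairs if (p[1], p[0]) not in present]
    # mutual dyads keep the orientation of their first occurrence in edge
    # order, so the procedure is exactly invariant under node relabeling
    mutuals = []
    seen_mutual: set[tuple[str, str]] = set()
    for p in all_pairs:
        if (p[1], p[0]) in present and p not in seen_mutual:
            mutuals.append(p)
            seen_mutual.add(p)
            seen_mutual.add((p[1], p[0]))

    # single-arc swaps: never create a reciprocal pair
    n_single = len(singles)
    if n_single >= 2:
        idx = rng.integers(0, n_single, size=(swap_factor * n_single, 2))
        for i, j in idx:
            if i == j:
                continue
            a, b = singles[i]
            c, d = singles[j]
            if a == d or c == b:
                continue
            new1, new2 = (a, d), (c, b)
            if new1 in present or new2 in present:
                continue
            if (d, a) in present or (b, c) in present:
                continue  # would create a mutual dyad
            present.difference_update(((a, b), (c, d)))
            present.update((new1, new2))
            singles[i], singles[j] = new1, new2

    # mutual-dyad swaps: rewire whole reciprocal pairs together
    n_mutual = len(mutuals)
    if n_mutual >= 2:
        idx = rng.integers(0, n_mutual, size=(swap_factor * n_mutual, 2))
        for i, j in idx:
            if i == j:
                continue
            a, b = mutuals[i]
            c, d = mutuals[j]
            # rewire {a,b},{c,d} -> {a,d},{c,b}
            if a == d or c == b:
                continue
            touched = [(a, d), (d, a), (c, b), (b, c)]
            if any(p in present for p in touched):
                continue
            present.difference_update(((a, b), (b, a), (c, d), (d, c)))
            present.update(touched)
            mutuals[i] = (a, d)
            mutuals[j] = (c, b)

    out_pairs = list(singles)
    for a, b in mutuals:
        out_pairs += [(a, b), (b, a)]
    return DirectedGRN(
        edges=[GRNEdge(s, t) for s, t in out_pairs],
        nodes=set(net.nodes),
        provenance=f"randomized(swap_factor={swap_factor},seed={seed})",
    )


def erdos_renyi_null(net: DirectedGRN, seed: int = 0) -> DirectedGRN:
    """Same-node, same-edge-count uniform random digraph (alternative null)."""
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    n = len(nodes)
    m = len(net.edges)
    possible = n * (n - 1)
    if m > possible:
        raise ValueError("more edges than loop-free pairs")
    codes = rng.choice(possible, size=m, replace=False)
    edges = []
    for k in codes:
        i, rest = divmod(int(k), n - 1)
        j = rest + (rest >= i)
        edges.append(GRNEdge(nodes[i], nodes[j]))
    return DirectedGRN(edges=edges, nodes=set(nodes), provenance=f"er_null(seed={seed})")


@dataclass
class MotifEnrichment:
    """Z-score of one motif class against the randomized ensemble."""

    motif_class: str
    count_real: int
    mean_random: float
    sd_random: float
    z_score: float
    enriched: bool


def motif_enrichment(
    net: DirectedGRN,
    n_random: int = DEFAULT_N_RANDOM,
    z_threshold: float = Z_THRESHOLD,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
    null_model: str = "switching",
) -> list[MotifEnrichment]:
    """Test each of the 13 classes against ``n_random`` randomized networks.

    ``z = (count_real - mean_random) / sd_random``; a class with zero
    randomized standard deviation is reported with z = 0 and cannot be
    enriched. ``null_model`` is "switching" (degree-preserving, default) or
    "erdos_renyi" (same node and edge counts only).
    """
    if n_random < 2:
        raise ValueError("need n_random >= 2 to estimate a standard deviation")
    if null_model not in ("switching", "erdos_renyi"):
        raise ValueError("null_model must be 'switching' or 'erdos_renyi'")
    real = census(net, with_instances=False)
    seeds = np.random.SeedSequence(seed).generate_state(n_random) % (2**31 - 1)
    rand_counts = np.zeros((n_random, len(MOTIF_CLASSES)))
    for i in range(n_random):
        null_net = (
            randomize(net, swap_factor, int(seeds[i]))
            if null_model == "switching"
            else erdos_renyi_null(net, int(seeds[i]))
        )
        c = census(null_net, with_instances=False)
        rand_counts[i] = [c[name][0] for name in MOTIF_CLASSES]

    mean = rand_counts.mean(axis=0)
    sd = rand_counts.std(axis=0, ddof=1)
    out = []
    for k, name in enumerate(MOTIF_CLASSES):
        count_real = real[name][0]
        if sd[k] > 0:
            z = float((count_real - mean[k]) / sd[k])
            enriched = z > z_threshold
        else:
            z = 0.0
            enriched = False
        out.append(MotifEnrichment(name, count_real, float(mean[k]), float(sd[k]), z, enriched))
    return out


def nms(net: DirectedGRN, enrichment: list[MotifEnrichment]) -> dict[str, int]:
    """Network motif score: per gene, the number of enriched-class instances
    containing it. Genes in no enriched instance are absent from the table."""
    enriched_classes = {e.motif_class for e in enrichment if e.enriched}
    if not enriched_classes:
        return {}
    full = census(net, with_instances=True)
    scores: dict[str, int] = {}
    for name in enriched_classes:
        for instance in full[name][1]:
            for gene in instance:
                scores[gene] = scores.get(gene, 0) + 1
    return scores


def total_motif_instances(net: DirectedGRN) -> int:
    """Total number of weakly connected triples (all classes combined)."""
    return sum(count for count, _ in census(net, with_instances=False).values())
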