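"""Tree-ensemble GRN inference with iteration consensus and sign assignment.

GENIE3-style ranking: for every target gene a random-forest regressor
predicts its expression across all samples from the expression of the
candidate regulators (the target itself excluded); the total variance
reduction attributed to each regulator, normalized per target, is the edge
importance. Several independent forest iterations are thresholded and
combined by majority consensus, and each surviving edge receives a sign
(promoting / repressing / regulating) from the Pearson correlation of the
source and target time-point mean profiles — the time-course element of the
procedure.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .containers import (
    PROMOTING,
    REGULATING,
    REPRESSING,
    DirectedGRN,
    ExpressionMatrix,
    GRNEdge,
)

DEFAULT_ITERATIONS = 5
DEFAULT_ENSEMBLE_SIZE = 300
DEFAULT_TOP_FRACTION = 0.05
DEFAULT_SIGN_TAU = 0.3


def tree_importance_matrix(
    expr: ExpressionMatrix,
    regulators: Iterable[str],
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Regulator x target matrix of random-forest importances.

    Each target column is fit independently; importances are impurity
    (variance) reductions normalized to sum to one over the candidate
    regulators. A zero-variance target yields an all-zero column. Self
    entries are held at zero.
    """
    regulators = list(regulators)
    genes = expr.genes
    gene_set = set(genes)
    missing = [r for r in regulators if r not in gene_set]
    if missing:
        raise ValueError(f"regulators not in expression matrix: {missing[:5]}")
    if expr.values.shape[1] < 4:
        raise ValueError("need at least 4 samples for tree-ensemble fitting")
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be positive")

    x_all = expr.values.loc[regulators].to_numpy(dtype=float).T  # samples x regulators
    imp = pd.DataFrame(0.0, index=pd.Index(regulators, name="regulator"),
                       columns=pd.Index(genes, name="target"))
    reg_pos = {r: i for i, r in enumerate(regulators)}
    child_seeds = np.random.SeedSequence(seed).generate_state(len(genes)) % (2**31 - 1)

    for j, target in enumerate(genes):
        y = expr.values.loc[target].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        cand = [r for r in regulators if r != target]
        if not cand:
            continue
        cols = [reg_pos[r] for r in cand]
        x = x_all[:, cols]
        # bootstrap resampling alone randomizes the ensemble; considering
        # every candidate at each split keeps irrelevant regulators from
        # accruing importance through forced splits
        forest = RandomForestRegressor(
            n_estimators=ensemble_size,
            max_features=1.0,
            random_state=int(child_seeds[j]),
            n_jobs=1,
        )
        forest.fit(x, y)
        importances = forest.feature_importances_
        total = importances.sum()
        if total > 0:
            importances = importances / total
        imp.loc[cand, target] = importances
    return imp


def _off_diagonal_values(imp: pd.DataFrame) -> np.ndarray:
    vals = []
    for r in imp.index:
        for t in imp.columns:
            if r != t:
                vals.append(imp.at[r, t])
    return np.asarray(vals, dtype=float)


def threshold_edges(imp: pd.DataFrame, top_fraction: float = DEFAULT_TOP_FRACTION) -> set[tuple[str, str]]:
    """Retain the top ``top_fraction`` of regulator->target pairs by importance.

    The cutoff is the (1 - top_fraction) lower quantile of all off-diagonal
    importances; pairs at or above the cutoff are kept (ties at the cutoff
    included), zero-importance pairs never are.
    """
    if imp.size == 0:
        raise ValueError("empty importance matrix")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    off = _off_diagonal_values(imp)
    if off.size == 0:
        raise ValueError("importance matrix has no off-diagonal entries")
    cutoff = np.quantile(off, 1.0 - top_fraction, method="lower")
    edges: set[tuple[str, str]] = set()
    for r in imp.index:
        for t in imp.columns:
            if r == t:
                continue
            v = imp.at[r, t]
            if v > 0 and v >= cutoff:
                edges.add((r, t))
    return edges


def consensus_edges(
    edge_sets: Sequence[set[tuple[str, str]]], min_support: int | None = None
) -> dict[tuple[str, str], int]:
    """Edges appearing in at least ``min_support`` of the per-iteration sets.

    Defaults to a majority rule, ``ceil(k / 2)`` for k iterations. Returns
    the surviving edges with their support counts.
    """
    if not edge_sets:
        raise ValueError("no edge sets given")
    k = len(edge_sets)
    if min_support is None:
        min_support = math.ceil(k / 2)
    if not 1 <= min_support <= k:
        raise ValueError("min_support must lie in [1, number of edge sets]")
    counts: dict[tuple[str, str], int] = {}
    for s in edge_sets:
        for e in s:
            counts[e] = counts.get(e, 0) + 1
    return {e: c for e, c in counts.items() if c >= min_support}


def assign_signs(
    edges: Iterable[tuple[str, str]] | Mapping[tuple[str, str], int],
    means: pd.DataFrame,
    tau: float = DEFAULT_SIGN_TAU,
    weights: Mapping[tuple[str, str], float] | None = None,
    provenance: str = "trees",
) -> DirectedGRN:
    """Label each edge from the correlation of source/target mean profiles.

    Pearson r above ``tau`` is promoting, below ``-tau`` repressing,
    anything in the dead zone (or involving a zero-variance profile) is
    just regulating. ``means`` has genes in rows and time points in columns.
    """
    support = edges if isinstance(edges, Mapping) else {e: 1 for e in edges}
    out: list[GRNEdge] = []
    for (src, tgt), sup in sorted(support.items()):
        if src not in means.index or tgt not in means.index:
            raise ValueError(f"missing mean profile for edge {src}->{tgt}")
        a = means.loc[src].to_numpy(dtype=float)
        b = means.loc[tgt].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            sign = REGULATING
        else:
            r = float(np.corrcoef(a, b)[0, 1])
            sign = PROMOTING if r > tau else REPRESSING if r < -tau else REGULATING
        w = weights.get((src, tgt), 1.0) if weights is not None else 1.0
        out.append(GRNEdge(src, tgt, weight=float(w), sign=sign, support=int(sup)))
    return DirectedGRN(edges=out, provenance=provenance)


def infer_rtp_star(
    expr: ExpressionMatrix,
    regulators: Iterable[str] | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    tau: float = DEFAULT_SIGN_TAU,
    min_support: int | None = None,
    seed: int = 0,
) -> DirectedGRN:
    """Full tree-ensemble inference: iterate, threshold, take consensus, sign.

    ``regulators`` defaults to every gene (the all-genes candidate set); a
    TF-only run passes the annotated TF set. Edge weights are mean
    importances over iterations; provenance records all parameters.
    """
    if iterations < 1:
        raise ValueError("iterations must be positive")
    regulators = list(regulators) if regulators is not None else expr.genes
    iter_seeds = np.random.SeedSequence(seed).generate_state(iterations) % (2**31 - 1)

    per_iter_edges: list[set[tuple[str, str]]] = []
    imp_sum: pd.DataFrame | None = None
    for it in range(iterations):
        imp = tree_importance_matrix(expr, regulators, ensemble_size, int(iter_seeds[it]))
        imp_sum = imp if imp_sum is None else imp_sum + imp
        per_iter_edges.append(threshold_edges(imp, top_fraction))
    supported = consensus_edges(per_iter_edges, min_support)
    mean_imp = imp_sum / iterations
    weights = {e: float(mean_imp.at[e[0], e[1]]) for e in supported}
    provenance = (
        f"trees(iterations={iterations},ensemble_size={ensemble_size},"
        f"top_fraction={top_fraction},tau={tau},seed={seed})"
    )
    return assign_signs(
        supported, expr.time_point_means(), tau=tau, weights=weights, provenance=provenance
    )
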