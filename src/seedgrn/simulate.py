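"""Synthetic ground-truth networks and expression data.

The generators emulate the statistical structure the downstream analysis
assumes: a sparse signed regulator->target network, a positive and noisy
replicate-structured developmental time course driven by that network, and
a two-condition overdispersed count experiment with a known enriched subset.
They exist so that every stage of the pipeline can be exercised against a
known truth without any sequencing data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, GroundTruthNetwork, TrueEdge

#: default developmental sampling grid, in days after pollination
DEFAULT_TIME_POINTS: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 7.0, 8.0)
DEFAULT_N_REPLICATES = 3


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def sample_ground_truth_network(
    n_genes: int,
    n_regulators: int,
    avg_out_degree: float,
    repressor_fraction: float = 0.0,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Draw a sparse signed regulator->target network.

    Each of the ``n_regulators * (n_genes - 1)`` loop-free regulator->gene
    pairs becomes an edge independently with probability
    ``avg_out_degree / (n_genes - 1)``, so the expected edge count is
    ``n_regulators * avg_out_degree``. A fraction ``repressor_fraction`` of
    edges carries sign -1; strengths are uniform on [0.5, 1.5].
    """
    if n_genes < 2 or n_regulators < 1 or n_regulators > n_genes:
        raise ValueError("need n_genes >= 2 and 1 <= n_regulators <= n_genes")
    if not 0.0 <= repressor_fraction <= 1.0:
        raise ValueError("repressor_fraction must lie in [0, 1]")
    if avg_out_degree <= 0 or avg_out_degree > n_genes - 1:
        raise ValueError(
            f"avg_out_degree must lie in (0, {n_genes - 1}] for {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    regulators = genes[:n_regulators]
    p = avg_out_degree / (n_genes - 1)
    edges: list[TrueEdge] = []
    for src in regulators:
        for tgt in genes:
            if tgt == src:
                continue
            if rng.random() < p:
                sign = -1 if rng.random() < repressor_fraction else 1
                strength = float(rng.uniform(0.5, 1.5))
                edges.append(TrueEdge(src, tgt, sign, strength))
    return GroundTruthNetwork(genes=genes, regulators=regulators, edges=edges)


def _gp_trajectories(
    rng: np.random.Generator, n: int, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Smooth exogenous developmental curves, one row per gene.

    Log-Gaussian-process curves: a zero-mean GP with an RBF kernel of the
    given bandwidth (in days) is exponentiated and scaled by a random
    per-gene amplitude, giving positive, smooth profiles whose shapes are
    diverse across genes — developmental waves peaking at different stages
    rather than a single shared trend.
    """
    k = np.exp(-((grid[:, None] - grid[None, :]) ** 2) / (2.0 * bandwidth**2))
    chol = np.linalg.cholesky(k + 1e-8 * np.eye(grid.size))
    z = (chol @ rng.normal(size=(grid.size, n))).T
    z -= z.mean(axis=1, keepdims=True)
    scale = rng.uniform(0.5, 3.0, size=n)
    return scale[:, None] * np.exp(z)


def _gp_deviations(
    rng: np.random.Generator, n: int, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Unit-variance smooth GP draws, one row per gene (log-scale deviations)."""
    k = np.exp(-((grid[:, None] - grid[None, :]) ** 2) / (2.0 * bandwidth**2))
    chol = np.linalg.cholesky(k + 1e-8 * np.eye(grid.size))
    return (chol @ rng.normal(size=(grid.size, n))).T


def simulate_time_course(
    net: GroundTruthNetwork,
    time_points: tuple[float, ...] | list[float] = DEFAULT_TIME_POINTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    noise_sd: float = 0.2,
    seed: int = 0,
    trajectory_bandwidth: float | None = None,
    internal_steps_per_unit: int = 4,
) -> ExpressionMatrix:
    """Simulate replicate-structured time-course expression from a network.

    Regulators (and non-regulator genes without incoming edges) follow
    smooth exogenous log-GP trajectories; each biological replicate carries
    its own smooth multiplicative deviation from the shared curve, with
    log-scale amplitude ``noise_sd``, emulating replicate-to-replicate
    biological variation. The network dynamics are propagated per replicate
    on a fine internal time grid (``internal_steps_per_unit`` steps per
    day): a regulated gene's expression at each internal step is a clipped
    linear response — monotone increasing, zero-bounded — to its
    standardized signed strength-weighted regulator sum at the previous
    step. Regulation is therefore fast relative to the ~2-day sampling
    interval, and biological replicate variation propagates from regulators
    to their targets — the two structural features the downstream
    concurrent-sample inference relies on. Trajectories are read off at the
    requested observation time points, and iid Gaussian measurement noise
    of standard deviation ``noise_sd / 2`` is added, clamped at zero —
    biological variation dominating technical noise, as in replicated
    RNA-seq at moderate expression levels. With
    ``noise_sd=0`` the simulation is fully deterministic across replicates.

    ``trajectory_bandwidth`` is the RBF bandwidth of the exogenous curves in
    days (default: a fifth of the time-course span).
    """
    if not net.genes:
        raise ValueError("network is empty")
    if len(time_points) < 2:
        raise ValueError("need at least 2 time points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")

    rng = np.random.default_rng(seed)
    tp = np.asarray(sorted(set(time_points)), dtype=float)
    if tp.size < 2:
        raise ValueError("need at least 2 distinct time points")
    span = tp.max() - tp.min()
    if trajectory_bandwidth is None:
        trajectory_bandwidth = span / 5.0
    dt = 1.0 / internal_steps_per_unit
    fine = np.arange(tp.min(), tp.max() + dt / 2.0, dt)
    # make sure every observation time is on the internal grid
    fine = np.unique(np.concatenate([fine, tp]))

    genes = net.genes
    n_genes = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    reg_set = set(net.regulators)
    incoming: dict[str, list[TrueEdge]] = {}
    for e in net.edges:
        incoming.setdefault(e.target, []).append(e)

    exogenous = [g for g in genes if g in reg_set or g not in incoming]
    curves = _gp_trajectories(rng, len(exogenous), fine, trajectory_bandwidth)
    # smooth per-replicate biological deviations on the log scale
    if noise_sd > 0:
        dev = noise_sd * np.stack(
            [
                _gp_deviations(rng, len(exogenous), fine, trajectory_bandwidth)
                for _ in range(n_replicates)
            ]
        )
    else:
        dev = np.zeros((n_replicates, len(exogenous), fine.size))

    # per-target response parameters: baseline and gain of the clipped
    # linear response, drawn once per regulated gene
    regulated = [g for g in genes if g not in reg_set and g in incoming]
    baseline = rng.uniform(1.0, 2.0, size=len(regulated))
    gain = rng.uniform(0.8, 1.5, size=len(regulated))

    # drive standardization constants come from the replicate-average
    # trajectories so every replicate sees the same response function
    shared = np.zeros((n_genes, fine.size))
    for row, g in enumerate(exogenous):
        shared[idx[g]] = curves[row]
    drive_stats: dict[str, tuple[float, float]] = {}
    for g in regulated:
        drive = np.zeros(fine.size)
        for e in incoming[g]:
            drive += e.sign * e.strength * shared[idx[e.source]]
        drive_stats[g] = (float(drive.mean()), float(drive.std()))

    traj = np.zeros((n_replicates, n_genes, fine.size))
    for r in range(n_replicates):
        for row, g in enumerate(exogenous):
            traj[r, idx[g]] = curves[row] * np.exp(dev[r, row])
        for k, g in enumerate(regulated):
            drive = np.zeros(fine.size)
            for e in incoming[g]:
                drive += e.sign * e.strength * traj[r, idx[e.source]]
            mu, sd = drive_stats[g]
            z = (drive - mu) / sd if sd > 0 else drive - mu
            lagged = np.concatenate([[z[0]], z[:-1]])
            traj[r, idx[g]] = np.maximum(0.0, baseline[k] + gain[k] * lagged)

    obs_idx = np.searchsorted(fine, tp)
    columns, time_col, rep_col = [], [], []
    data = np.zeros((n_genes, tp.size * n_replicates))
    col = 0
    for j, t in enumerate(tp):
        for r in range(1, n_replicates + 1):
            noise = rng.normal(0.0, 0.5 * noise_sd, size=n_genes) if noise_sd > 0 else 0.0
            data[:, col] = np.maximum(0.0, traj[r - 1, :, obs_idx[j]] + noise)
            columns.append(f"T{t:g}_R{r}")
            time_col.append(float(t))
            rep_col.append(r)
            col += 1

    values = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(
        {"sample_id": columns, "time_dap": time_col, "replicate": rep_col}
    )
    return ExpressionMatrix(values=values, samples=samples)


def simulate_two_condition_counts(
    n_genes: int,
    n_enriched: int,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    n_reps_per_group: int = 7,
    seed: int = 0,
) -> CountMatrix:
    """Simulate an endosperm vs whole-seed count contrast with known truth.

    Baseline per-gene means are log-normal (median around 55 counts);
    exactly ``n_enriched`` genes have their endosperm-group mean multiplied
    by ``2 ** effect_log2fc``. Counts are negative-binomial with the
    mean/dispersion parameterization (variance ``m + dispersion * m**2``);
    a vanishing dispersion falls back to Poisson sampling.
    """
    if n_enriched < 0 or n_enriched > n_genes:
        raise ValueError("need 0 <= n_enriched <= n_genes")
    if effect_log2fc <= 0:
        raise ValueError("effect_log2fc must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_reps_per_group < 2:
        raise ValueError("need >= 2 replicates per group for downstream testing")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    base_mean = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    enriched_idx = rng.choice(n_genes, size=n_enriched, replace=False)
    truth = np.zeros(n_genes, dtype=bool)
    truth[enriched_idx] = True

    endo_mean = base_mean.copy()
    endo_mean[truth] *= 2.0**effect_log2fc

    def draw(mean_vec: np.ndarray, n_cols: int) -> np.ndarray:
        m = np.tile(mean_vec[:, None], (1, n_cols))
        if dispersion < 1e-8:
            return rng.poisson(m)
        r = 1.0 / dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    endo = draw(endo_mean, n_reps_per_group)
    ws = draw(base_mean, n_reps_per_group)
    counts = np.concatenate([endo, ws], axis=1).astype(np.int64)

    sample_ids = [f"endo_{i+1}" for i in range(n_reps_per_group)] + [
        f"ws_{i+1}" for i in range(n_reps_per_group)
    ]
    groups = ["endosperm"] * n_reps_per_group + ["whole_seed"] * n_reps_per_group
    gene_index = pd.Index(genes, name="gene")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_index, columns=sample_ids),
        samples=pd.DataFrame({"sample_id": sample_ids, "group": groups}),
        truth=pd.Series(truth, index=gene_index, name="enriched_truth"),
    )
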