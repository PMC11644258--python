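"""End-to-end workflow binding filters, inference, motifs and comparison.

Mirrors the study design: one of three gene sets (endosperm-enriched + MSE,
MSE over all genes, or annotated TFs) is built from the inputs, one or both
inference engines run on the expression of that gene set, each network is
censused and tested for motif enrichment, per-gene motif scores are
computed, and — when both engines ran — their edge overlap is permutation
tested. Every output file carries a provenance header and all randomness
flows from the single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, filters, io, kboost, motifs, trees
from .compare import overlap_permutation_test, topology_summary
from .containers import CountMatrix, DirectedGRN, ExpressionMatrix

logger = logging.getLogger("seedgrn")

GENE_SET_CHOICES = ("enriched_mse", "mse_all", "tf")
ENGINE_CHOICES = ("trees", "kboost", "both")


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and the single seed for one pipeline run."""

    expression_path: Path
    sample_meta_path: Path
    out_dir: Path
    gene_set: str = "mse_all"
    engine: str = "both"
    # enrichment stage inputs (needed for gene_set="enriched_mse")
    counts_path: Path | None = None
    counts_meta_path: Path | None = None
    # TF stage inputs (needed for gene_set="tf")
    annotations_path: Path | None = None
    tf_identifiers_path: Path | None = None
    # stage parameters
    lfc_threshold: float = filters.LFC_THRESHOLD
    fdr_threshold: float = filters.FDR_THRESHOLD
    mse_threshold: float = filters.MSE_OUTLIER_THRESHOLD
    iterations: int = trees.DEFAULT_ITERATIONS
    ensemble_size: int = trees.DEFAULT_ENSEMBLE_SIZE
    top_fraction: float = trees.DEFAULT_TOP_FRACTION
    tau: float = trees.DEFAULT_SIGN_TAU
    boosting_rounds: int = kboost.DEFAULT_BOOSTING_ROUNDS
    n_components: int | None = None
    n_random: int = motifs.DEFAULT_N_RANDOM
    z_threshold: float = motifs.Z_THRESHOLD
    swap_factor: int = motifs.DEFAULT_SWAP_FACTOR
    n_permutations: int = 10_000
    directed_overlap: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.gene_set not in GENE_SET_CHOICES:
            raise ValueError(f"gene_set must be one of {GENE_SET_CHOICES}")
        if self.engine not in ENGINE_CHOICES:
            raise ValueError(f"engine must be one of {ENGINE_CHOICES}")
        if self.gene_set == "enriched_mse" and (
            self.counts_path is None or self.counts_meta_path is None
        ):
            raise ValueError("gene_set 'enriched_mse' needs counts_path and counts_meta_path")
        if self.gene_set == "tf" and (
            self.annotations_path is None or self.tf_identifiers_path is None
        ):
            raise ValueError("gene_set 'tf' needs annotations_path and tf_identifiers_path")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        for name in ("fdr_threshold", "mse_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def provenance(self, **extra: object) -> dict[str, object]:
        base: dict[str, object] = {
            "seedgrn_version": __version__,
            "seed": self.seed,
            "gene_set": self.gene_set,
            "engine": self.engine,
        }
        base.update(extra)
        return base


def _build_gene_set(cfg: PipelineConfig, expr: ExpressionMatrix) -> set[str]:
    means = expr.time_point_means()
    if cfg.gene_set == "mse_all":
        selected = filters.mse_filter(means, cfg.mse_threshold)
        logger.info("MSE filter retained %d of %d genes", len(selected), len(expr.genes))
        return selected
    if cfg.gene_set == "enriched_mse":
        counts = io.read_counts(cfg.counts_path, cfg.counts_meta_path)
        _check_gene_ids(expr, counts)
        records = filters.attach_fdr(filters.differential_enrichment(counts))
        enriched = filters.classify_enriched(records, cfg.lfc_threshold, cfg.fdr_threshold)
        io.write_enrichment_table(
            records, cfg.out_dir / "enrichment_table.tsv", cfg.provenance(stage="enrichment")
        )
        logger.info("enrichment classified %d of %d genes", len(enriched), len(records))
        candidates = enriched & set(expr.genes)
        selected = filters.mse_filter(means.loc[sorted(candidates)], cfg.mse_threshold)
        logger.info("MSE filter retained %d of %d enriched genes", len(selected), len(candidates))
        return selected
    # tf
    annotations = io.read_annotations(cfg.annotations_path)
    tf_ids = io.read_gene_set(cfg.tf_identifiers_path)
    if not tf_ids:
        raise ValueError("empty TF identifier list")
    tfs = filters.select_tfs(annotations, tf_ids) & set(expr.genes)
    logger.info("TF selection retained %d genes", len(tfs))
    if not tfs:
        raise ValueError("TF selection produced an empty gene set")
    return tfs


def _check_gene_ids(expr: ExpressionMatrix, counts: CountMatrix) -> None:
    missing = sorted(set(expr.genes) - set(counts.genes))
    if missing:
        raise ValueError(
            f"{len(missing)} expression genes absent from the count matrix, "
            f"e.g. {missing[:5]}"
        )


def _motif_stage(cfg: PipelineConfig, net: DirectedGRN, label: str, seed: int) -> None:
    enr = motifs.motif_enrichment(
        net, n_random=cfg.n_random, z_threshold=cfg.z_threshold,
        swap_factor=cfg.swap_factor, seed=seed,
    )
    prov = cfg.provenance(stage=f"motifs_{label}", n_random=cfg.n_random,
                          z_threshold=cfg.z_threshold)
    io.write_motif_enrichment(enr, cfg.out_dir / f"motif_enrichment_{label}.tsv", prov)
    full_census = motifs.census(net, with_instances=True)
    io.write_motif_instances(full_census, cfg.out_dir / f"motif_instances_{label}.tsv", prov)
    io.write_nms(motifs.nms(net, enr), cfg.out_dir / f"nms_{label}.tsv", prov)
    io.write_topology_summary(topology_summary(net), cfg.out_dir / f"topology_{label}.tsv")
    n_enriched = sum(e.enriched for e in enr)
    logger.info("%s: %d motif classes enriched (Z > %.1f)", label, n_enriched, cfg.z_threshold)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured workflow; returns the output directory."""
    cfg.validate()
    cfg.out_dir = Path(cfg.out_dir)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31 - 1)

    expr = io.read_expression(cfg.expression_path, cfg.sample_meta_path)
    logger.info("expression: %d genes x %d samples", *expr.values.shape)

    selected = _build_gene_set(cfg, expr)
    if not selected:
        raise ValueError("selected gene set is empty; nothing to infer")
    io.write_gene_set(selected, cfg.out_dir / "gene_set.txt", cfg.provenance(stage="gene_set"))
    sub = expr.subset(selected)

    nets: dict[str, DirectedGRN] = {}
    if cfg.engine in ("trees", "both"):
        nets["trees"] = trees.infer_rtp_star(
            sub, iterations=cfg.iterations, ensemble_size=cfg.ensemble_size,
            top_fraction=cfg.top_fraction, tau=cfg.tau, seed=int(seeds[0]),
        )
    if cfg.engine in ("kboost", "both"):
        post = kboost.infer_kboost(
            sub, n_components=cfg.n_components, boosting_rounds=cfg.boosting_rounds,
        )
        with open(cfg.out_dir / "kboost_posterior.tsv", "w") as fh:
            for k, v in cfg.provenance(stage="kboost_posterior").items():
                fh.write(f"# {k}: {v}\n")
            post.to_csv(fh, sep="\t", float_format="%.9g")
        nets["kboost"] = kboost.select_top_regulators(post)

    for label, net in nets.items():
        logger.info("%s network: %d nodes, %d edges", label, len(net.nodes), len(net.edges))
        prov = cfg.provenance(stage=f"network_{label}", provenance=net.provenance)
        io.write_edge_list(net, cfg.out_dir / f"network_{label}.tsv", prov)
        io.write_sif(net, cfg.out_dir / f"network_{label}.sif")
        _motif_stage(cfg, net, label, int(seeds[1]))

    if len(nets) == 2:
        result = overlap_permutation_test(
            nets["trees"], nets["kboost"], gene_universe=set(sub.genes),
            n_permutations=cfg.n_permutations, directed=cfg.directed_overlap,
            seed=int(seeds[2]),
        )
        io.write_overlap_report(
            result, cfg.out_dir / "overlap_report.tsv", cfg.out_dir / "overlap_report.json",
            cfg.provenance(stage="overlap", n_permutations=cfg.n_permutations),
        )
        logger.info(
            "overlap: %d shared edges (%.1f%%), p = %.4g",
            result.observed_overlap, 100 * result.overlap_fraction, result.p_value,
        )
    return cfg.out_dir
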