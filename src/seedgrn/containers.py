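"""Core in-memory containers shared across the pipeline.

Expression and count data are held as pandas DataFrames (genes in rows,
samples in columns) with a companion sample-metadata table; networks are
lightweight edge-list objects rather than full graph structures, because
every downstream operation (censusing, randomization, overlap counting)
works on the edge list directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sign labels a regulatory edge may carry
PROMOTING = "promoting"
REPRESSING = "repressing"
REGULATING = "regulating"
EDGE_SIGNS = (PROMOTING, REPRESSING, REGULATING)


@dataclass(frozen=True)
class TrueEdge:
    """A ground-truth regulator->target interaction with sign and strength."""

    source: str
    target: str
    sign: int  # +1 activating, -1 repressing
    strength: float


@dataclass
class GroundTruthNetwork:
    """A known sparse signed regulatory network used to drive simulations."""

    genes: list[str]
    regulators: list[str]
    edges: list[TrueEdge]

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        reg_set = set(self.regulators)
        if not reg_set <= gene_set:
            raise ValueError("regulators must be a subset of genes")
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-loop on {e.source}")
            if e.source not in reg_set:
                raise ValueError(f"edge source {e.source} is not a regulator")
            if e.target not in gene_set:
                raise ValueError(f"edge target {e.target} is not a known gene")
            if (e.source, e.target) in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            if e.strength <= 0:
                raise ValueError("edge strengths must be positive")
            if e.sign not in (1, -1):
                raise ValueError("edge sign must be +1 or -1")
            seen.add((e.source, e.target))

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (FPKM-like) with time-course metadata.

    ``samples`` has one row per column of ``values`` with columns
    ``sample_id``, ``time_dap`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "time_dap", "replicate"}
        if not required <= set(self.samples.columns):
            raise ValueError(f"sample metadata needs columns {sorted(required)}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("value columns must match metadata sample_id order")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("expression values must be finite and non-negative")
        pairs = list(zip(self.samples["time_dap"], self.samples["replicate"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("(time point, replicate) pairs must be unique")
        if self.samples["time_dap"].nunique() < 2:
            raise ValueError("at least 2 time points are required")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_points(self) -> list[float]:
        return sorted(self.samples["time_dap"].unique())

    def time_point_means(self) -> pd.DataFrame:
        """Mean expression per gene at each time point (columns sorted by time)."""
        groups = self.values.T.groupby(self.samples.set_index("sample_id")["time_dap"])
        means = groups.mean().T
        return means[sorted(means.columns)]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.samples.copy())


@dataclass
class CountMatrix:
    """Gene x sample raw counts for a two-group contrast.

    ``samples`` has columns ``sample_id`` and ``group`` (``endosperm`` vs
    ``whole_seed``); ``truth`` optionally flags the genes simulated as
    genuinely enriched.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.Series | None = None

    def __post_init__(self) -> None:
        if not {"sample_id", "group"} <= set(self.samples.columns):
            raise ValueError("count metadata needs sample_id and group columns")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns must match metadata sample_id order")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.truth is not None and not self.truth.index.equals(self.counts.index):
            raise ValueError("truth flags must be indexed by the count genes")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == group, "sample_id"])


@dataclass(frozen=True)
class GRNEdge:
    """A directed, weighted, optionally signed inferred regulation."""

    source: str
    target: str
    weight: float = 1.0
    sign: str = REGULATING
    support: int = 1


@dataclass
class DirectedGRN:
    """An inferred directed network: ordered edge list plus node set.

    Edge order is preserved as given (it is the unit of reproducibility for
    degree-preserving randomization); duplicates and self-loops are rejected.
    """

    edges: list[GRNEdge]
    nodes: set[str] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-loop on {e.source}")
            pair = (e.source, e.target)
            if pair in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            if e.sign not in EDGE_SIGNS:
                raise ValueError(f"unknown sign label {e.sign!r}")
            seen.add(pair)
        endpoint_nodes = {e.source for e in self.edges} | {e.target for e in self.edges}
        if not self.nodes:
            self.nodes = endpoint_nodes
        elif not endpoint_nodes <= self.nodes:
            raise ValueError("every edge endpoint must be in the node set")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def edge_pairs(self) -> list[tuple[str, str]]:
        return [(e.source, e.target) for e in self.edges]

    def edge_pair_set(self) -> set[tuple[str, str]]:
        return set(self.edge_pairs)

    def relabel(self, mapping: Mapping[str, str]) -> "DirectedGRN":
        """Consistently rename nodes, preserving edge order."""
        edges = [
            GRNEdge(mapping[e.source], mapping[e.target], e.weight, e.sign, e.support)
            for e in self.edges
        ]
        nodes = {mapping[n] for n in self.nodes}
        return DirectedGRN(edges, nodes, self.provenance)


@dataclass
class EnrichmentRecord:
    """Per-gene differential-enrichment statistics for the two-group contrast."""

    gene: str
    log2fc: float
    p_raw: float
    p_fdr: float | None = None
    enriched: bool | None = None


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records (genes in rows)."""
    return pd.DataFrame(
        {
            "log2fc": [r.log2fc for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_fdr": [r.p_fdr for r in records],
            "enriched": [r.enriched for r in records],
        },
        index=pd.Index([r.gene for r in records], name="gene"),
    )
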