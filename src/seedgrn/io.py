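"""Flat-file readers and writers: TSV throughout, SIF for network viewers.

Every writer can prepend ``#``-prefixed provenance header lines (package
version, seed, parameters); every reader skips them. Floats are written at
9 significant digits so a write/read round trip reproduces values to text
precision. CRLF and LF line endings are both accepted.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import OverlapResult, TopologySummary
from .containers import (
    CountMatrix,
    DirectedGRN,
    EnrichmentRecord,
    ExpressionMatrix,
    GRNEdge,
    GroundTruthNetwork,
    TrueEdge,
    enrichment_frame,
)
from .motifs import MotifEnrichment

_FLOAT_FMT = "%.9g"


def _header_lines(provenance: Mapping[str, object] | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def _write_frame(df: pd.DataFrame, path: Path, provenance: Mapping[str, object] | None,
                 index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance))
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index=index)


def _read_table(path: Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except ValueError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def _check_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric cell in {path} at gene {row!r}, column {col!r}")
        df[col] = converted
    return df


# -- expression / counts ----------------------------------------------------

def write_expression(
    expr: ExpressionMatrix, values_path: str | Path, samples_path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    _write_frame(expr.values, Path(values_path), provenance)
    _write_frame(expr.samples, Path(samples_path), provenance, index=False)


def read_expression(values_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    values = _read_table(Path(values_path), index_col=0)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {values_path}")
    values = _check_numeric(values, Path(values_path))
    samples = _read_table(Path(samples_path))
    samples["sample_id"] = samples["sample_id"].astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, samples=samples)


def write_counts(
    counts: CountMatrix, counts_path: str | Path, samples_path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    _write_frame(counts.counts, Path(counts_path), provenance)
    _write_frame(counts.samples, Path(samples_path), provenance, index=False)


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    mat = _read_table(Path(counts_path), index_col=0)
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {counts_path}")
    mat = _check_numeric(mat, Path(counts_path)).astype(np.int64)
    samples = _read_table(Path(samples_path))
    samples["sample_id"] = samples["sample_id"].astype(str)
    mat.columns = mat.columns.astype(str)
    return CountMatrix(counts=mat, samples=samples)


# -- ground-truth network ---------------------------------------------------

def write_ground_truth(
    net: GroundTruthNetwork, path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame(
        [(e.source, e.target, e.sign, e.strength) for e in net.edges],
        columns=["source", "target", "sign", "strength"],
    )
    _write_frame(df, Path(path), provenance, index=False)


def read_ground_truth(
    path: str | Path, genes: Sequence[str] | None = None,
    regulators: Sequence[str] | None = None,
) -> GroundTruthNetwork:
    df = _read_table(Path(path), dtype={"source": str, "target": str})
    edges = [
        TrueEdge(r.source, r.target, int(r.sign), float(r.strength))
        for r in df.itertuples()
    ]
    if regulators is None:
        regulators = sorted({e.source for e in edges})
    if genes is None:
        genes = sorted({e.source for e in edges} | {e.target for e in edges})
    return GroundTruthNetwork(genes=list(genes), regulators=list(regulators), edges=edges)


# -- inferred networks ------------------------------------------------------

def write_edge_list(
    net: DirectedGRN, path: str | Path, provenance: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame(
        [(e.source, e.target, e.weight, e.sign, e.support) for e in net.edges],
        columns=["source", "target", "weight", "sign", "support"],
    )
    _write_frame(df, Path(path), provenance, index=False)


def read_edge_list(path: str | Path) -> DirectedGRN:
    df = _read_table(Path(path), dtype={"source": str, "target": str})
    edges = [
        GRNEdge(r.source, r.target, float(r.weight), str(r.sign), int(r.support))
        for r in df.itertuples()
    ]
    return DirectedGRN(edges=edges, provenance=str(path))


def write_sif(net: DirectedGRN, path: str | Path) -> None:
    """Simple interaction format: ``source sign-word target`` per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")


def read_sif(path: str | Path) -> DirectedGRN:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line {lineno} in {path}: {line!r}")
            src, sign, tgt = parts
            edges.append(GRNEdge(src, tgt, sign=sign))
    return DirectedGRN(edges=edges, provenance=str(path))


# -- gene sets, annotations, enrichment -------------------------------------

def write_gene_set(genes: Iterable[str], path: str | Path,
                   provenance: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance))
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_set(path: str | Path) -> set[str]:
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g, ";".join(sorted(ids))) for g, ids in sorted(annotations.items())],
        columns=["gene", "identifiers"],
    )
    _write_frame(df, Path(path), None, index=False)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    df = _read_table(Path(path), dtype=str).fillna("")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        if r.gene in out:
            raise ValueError(f"duplicate gene id {r.gene!r} in {path}")
        out[r.gene] = {tok for tok in str(r.identifiers).split(";") if tok}
    return out


def write_enrichment_table(
    records: Sequence[EnrichmentRecord], path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    _write_frame(enrichment_frame(records), Path(path), provenance)


def read_enrichment_table(path: str | Path) -> list[EnrichmentRecord]:
    df = _read_table(Path(path), index_col=0)
    records = []
    for gene, row in df.iterrows():
        records.append(
            EnrichmentRecord(
                gene=str(gene),
                log2fc=float(row["log2fc"]),
                p_raw=float(row["p_raw"]),
                p_fdr=None if pd.isna(row["p_fdr"]) else float(row["p_fdr"]),
                enriched=None if pd.isna(row["enriched"]) else bool(row["enriched"]),
            )
        )
    return records


# -- motif and overlap reports ----------------------------------------------

def write_motif_enrichment(
    enrichment: Sequence[MotifEnrichment], path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame(
        [
            (e.motif_class, e.count_real, e.mean_random, e.sd_random, e.z_score, e.enriched)
            for e in enrichment
        ],
        columns=["motif_class", "count_real", "mean_random", "sd_random", "z_score", "enriched"],
    )
    _write_frame(df, Path(path), provenance, index=False)


def write_motif_instances(
    census_result: Mapping[str, tuple[int, list[tuple[str, str, str]]]],
    path: str | Path, provenance: Mapping[str, object] | None = None,
) -> None:
    rows = []
    for cls, (_, instances) in sorted(census_result.items()):
        for inst in instances:
            rows.append((cls, *inst))
    df = pd.DataFrame(rows, columns=["motif_class", "node_a", "node_b", "node_c"])
    _write_frame(df, Path(path), provenance, index=False)


def write_nms(scores: Mapping[str, int], path: str | Path,
              provenance: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame(sorted(scores.items()), columns=["gene", "nms"])
    _write_frame(df, Path(path), provenance, index=False)


def write_overlap_report(
    result: OverlapResult, path_tsv: str | Path, path_json: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    d = asdict(result)
    df = pd.DataFrame([d])
    _write_frame(df, Path(path_tsv), provenance, index=False)
    payload = dict(d)
    if provenance:
        payload["provenance"] = {k: str(v) for k, v in provenance.items()}
    Path(path_json).parent.mkdir(parents=True, exist_ok=True)
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_topology_summary(summary: TopologySummary, path: str | Path) -> None:
    d = asdict(summary)
    hist = d.pop("in_degree_histogram")
    d["in_degree_histogram"] = json.dumps(hist)
    _write_frame(pd.DataFrame([d]), Path(path), None, index=False)
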