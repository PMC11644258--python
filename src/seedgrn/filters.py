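"""Gene-set construction: enrichment classification, entropy filtering, TF selection.

Three filters feed network inference. Endosperm-enrichment classification
flags genes whose expression is substantially higher in isolated endosperm
than in the whole seed (log2 fold change above 1.5 at FDR-adjusted p below
0.01). The Modified Shannon Entropy (MSE) filter keeps genes whose time
profile contains at least one low-entropy "outlier" value, i.e. genes with
dynamically specific expression. Transcription-factor selection is
table-driven matching of functional identifiers (GO/InterPro/PFam/PANTHER).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, EnrichmentRecord

#: default enrichment thresholds
LFC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.01
#: default MSE outlier threshold ("less than 30%")
MSE_OUTLIER_THRESHOLD = 0.30

# maximum of -q*log2(q) over q in (0,1], attained at q = 1/e
_MAX_POINT_ENTROPY = math.log2(math.e) / math.e


def _effective_library_sizes(mat: np.ndarray) -> np.ndarray:
    """Median-of-ratios effective library sizes, scaled to the raw totals.

    Each sample's size factor is the median ratio of its counts to the
    gene-wise geometric mean over genes expressed everywhere; factors are
    rescaled so their mean matches the mean raw library size. Falls back to
    raw totals when no gene is expressed in every sample.
    """
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a sample has zero total counts")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        return totals
    log_geo = np.log(mat[expressed]).mean(axis=1, keepdims=True)
    ratios = np.log(mat[expressed]) - log_geo
    log_factors = np.median(ratios, axis=0)
    # anchor on the geometric mean of the raw totals so that rescaling one
    # sample's counts rescales only that sample's effective size
    return np.exp(log_factors - log_factors.mean() + np.log(totals).mean())


def differential_enrichment(counts: CountMatrix) -> list[EnrichmentRecord]:
    """Per-gene fold change and p-value for the endosperm vs whole-seed contrast.

    A lightweight differential test: counts are normalized to counts per
    million (CPM) using median-of-ratios effective library sizes (robust to
    a subset of strongly enriched genes inflating one group's sequencing
    depth), log2 fold change is computed between pseudocounted group means
    of CPM, and the raw p-value comes from a Welch (unequal-variance)
    t-test on log2(CPM + 1). FDR adjustment is a separate step
    (:func:`bh_adjust` via :func:`attach_fdr`). The record interface also
    accepts externally computed (log2fc, p) tables, so output from a
    negative-binomial tool can be dropped in unchanged.
    """
    endo_cols = counts.group_columns("endosperm")
    ws_cols = counts.group_columns("whole_seed")
    if len(endo_cols) < 2 or len(ws_cols) < 2:
        raise ValueError("each group needs >= 2 samples (variance undefined otherwise)")

    mat = counts.counts.to_numpy(dtype=float)
    lib = _effective_library_sizes(mat)
    cpm = mat / lib * 1e6
    cpm_df = pd.DataFrame(cpm, index=counts.counts.index, columns=counts.counts.columns)

    endo = cpm_df[endo_cols].to_numpy()
    ws = cpm_df[ws_cols].to_numpy()
    pseudo = 0.5
    log2fc = np.log2(endo.mean(axis=1) + pseudo) - np.log2(ws.mean(axis=1) + pseudo)

    log_endo = np.log2(endo + 1.0)
    log_ws = np.log2(ws + 1.0)
    t_res = stats.ttest_ind(log_endo, log_ws, axis=1, equal_var=False)
    p_raw = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)

    return [
        EnrichmentRecord(gene=g, log2fc=float(l), p_raw=float(p))
        for g, l, p in zip(counts.genes, log2fc, p_raw)
    ]


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Fill the ``p_fdr`` field of enrichment records in place (and return them)."""
    adjusted = bh_adjust([r.p_raw for r in records])
    for r, q in zip(records, adjusted):
        r.p_fdr = float(q)
    return list(records)


def classify_enriched(
    records: Sequence[EnrichmentRecord],
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> set[str]:
    """Genes surpassing both thresholds: log2FC strictly above ``lfc_threshold``
    and FDR-adjusted p strictly below ``fdr_threshold``. Flags are set on the
    records as a side effect."""
    selected: set[str] = set()
    for r in records:
        if r.p_fdr is None:
            raise ValueError(f"record for {r.gene} lacks an FDR-adjusted p-value")
        r.enriched = bool(r.log2fc > lfc_threshold and r.p_fdr < fdr_threshold)
        if r.enriched:
            selected.add(r.gene)
    return selected


def mse_scores(means: np.ndarray) -> np.ndarray:
    """Normalized per-value entropy scores of one time profile.

    With p_t the profile normalized to sum 1, each value scores
    ``-p_t * log2(p_t)`` (0 at p_t = 0), divided by the maximum attainable
    point entropy log2(e)/e so that scores live on a fixed [0, 1]-ish scale
    and "below 30%" is scale-free. Low scores mark outlier values: either a
    dominating spike or a near-vanishing dip relative to the profile total.
    """
    means = np.asarray(means, dtype=float)
    if (means < 0).any():
        raise ValueError("time-point means must be non-negative")
    total = means.sum()
    if total == 0:
        raise ValueError("all-zero profile has no entropy distribution")
    p = means / total
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return e / _MAX_POINT_ENTROPY


def mse_filter(
    profiles: Mapping[str, np.ndarray] | pd.DataFrame,
    outlier_threshold: float = MSE_OUTLIER_THRESHOLD,
) -> set[str]:
    """Modified Shannon Entropy filter over per-time-point mean profiles.

    A gene is retained iff at least one of its normalized entropy scores
    falls below ``outlier_threshold`` — i.e. its profile records at least
    one outlier expression value across the time series. All-zero profiles
    are excluded.

    ``profiles`` maps gene id to a length-T vector of time-point means, or
    is a DataFrame with genes in rows and time points in columns.
    """
    if isinstance(profiles, pd.DataFrame):
        items: Iterable[tuple[str, np.ndarray]] = (
            (g, profiles.loc[g].to_numpy()) for g in profiles.index
        )
    else:
        items = profiles.items()
    retained: set[str] = set()
    for gene, means in items:
        means = np.asarray(means, dtype=float)
        if means.size < 2:
            raise ValueError(f"profile for {gene} has fewer than 2 time points")
        if (means < 0).any():
            raise ValueError(f"negative means for {gene}")
        if means.sum() == 0:
            continue
        if (mse_scores(means) < outlier_threshold).any():
            retained.add(gene)
    return retained


def select_tfs(
    annotations: Mapping[str, set[str]] | pd.Series,
    tf_identifiers: set[str] | Iterable[str],
) -> set[str]:
    """Genes whose functional-identifier set intersects the TF identifier list.

    Intersecting the result with an expressed-gene set is left to the caller.
    """
    tf_ids = set(tf_identifiers)
    if isinstance(annotations, pd.Series):
        annotations = annotations.to_dict()
    return {g for g, ids in annotations.items() if set(ids) & tf_ids}
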