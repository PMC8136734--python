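"""Count normalization and gene selection ahead of factorization.

Fixed stage order: counts-per-million normalization, removal of
non-expressed genes (CPM below a threshold in at least a given fraction of
samples), then retention of the top fraction of genes ranked by the
interquartile range of log2(CPM+1). The matrix handed to NMF holds CPM of
the selected genes (optionally log2(CPM+1)); it is always nonnegative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled to sum to 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-library samples: {list(zero.index)[:5]}")
    return counts * (1e6 / totals)


def filter_nonexpressed(
    counts: pd.DataFrame, cpm_threshold: float = 5.0, fraction: float = 0.8
) -> pd.Index:
    """Indices of genes kept after the low-expression filter.

    A gene is removed when its CPM is below ``cpm_threshold`` in at least
    ``fraction`` of the samples; kept genes are returned in original order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    cpm = normalize_cpm(counts)
    m = cpm.shape[1]
    n_below = (cpm.to_numpy() < cpm_threshold).sum(axis=1)
    keep = n_below < fraction * m - 1e-9
    kept = counts.index[keep]
    if len(kept) == 0:
        raise ValueError(
            "all genes removed by the expression filter; lower cpm_threshold"
        )
    logger.info(
        "expression filter (CPM<%g in >=%d%% of %d samples): %d -> %d genes",
        cpm_threshold, round(fraction * 100), m, len(counts), len(kept),
    )
    return kept


def gene_iqr(expr: pd.DataFrame) -> pd.Series:
    """Per-gene interquartile range of log2(CPM+1), linear interpolation."""
    logged = np.log2(expr.to_numpy() + 1.0)
    q1, q3 = np.percentile(logged, [25, 75], axis=1)
    return pd.Series(q3 - q1, index=expr.index, name="iqr")


def n_top_genes(n_genes: int, top_fraction: float) -> int:
    """Gene count at a fraction cutoff: floor(top_fraction * n_genes)."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    return int(np.floor(top_fraction * n_genes))


def select_by_iqr(expr: pd.DataFrame, top_fraction: float = 0.2) -> pd.DataFrame:
    """Keep the floor(top_fraction*n) genes with the largest IQR.

    IQR is computed on log2(CPM+1); ties are broken by original gene
    order; rows of the output keep the input ordering; values untouched.
    """
    n_keep = n_top_genes(len(expr), top_fraction)
    if n_keep == 0:
        raise ValueError("top_fraction keeps zero genes")
    iqr = gene_iqr(expr).to_numpy()
    # stable sort on -iqr: ties resolved by original gene order
    ranked = np.argsort(-iqr, kind="stable")[:n_keep]
    keep_mask = np.zeros(len(expr), dtype=bool)
    keep_mask[ranked] = True
    out = expr.loc[keep_mask]
    logger.info("IQR selection (top %.0f%%): %d -> %d genes",
                top_fraction * 100, len(expr), len(out))
    return out


def run_preprocess(
    counts: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, dict]:
    """Normalize, filter and select; returns the NMF input and provenance."""
    kept = filter_nonexpressed(
        counts, config.cpm_threshold, config.nonexpressed_fraction
    )
    cpm = normalize_cpm(counts).loc[kept]
    selected = select_by_iqr(cpm, config.iqr_top_fraction)
    if config.log_expression:
        selected = np.log2(selected + 1.0)
    provenance = {
        "n_genes_input": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_genes_expressed": int(len(kept)),
        "n_genes_selected": int(selected.shape[0]),
        "scale": "log2cpm1" if config.log_expression else "cpm",
    }
    return selected, provenance
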