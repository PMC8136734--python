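"""Subtype transfer to independent cohorts via signature-gene projection.

The discovery signature genes are projected onto the new expression
matrix, the projected matrix is consensus-NMF clustered, and each new
cluster is named after the discovery subtype whose signature genes it
most elevates (one-to-one matching maximizing the total mean standardized
signature score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import AnalysisConfig
from .consensus import ConsensusResult, consensus_matrix, select_k
from .signatures import SignatureSet

matplotlib.use("Agg")

logger = logging.getLogger(__name__)


@dataclass
class ProjectedDataset:
    matrix: pd.DataFrame  # signature-gene x sample, nonnegative
    matched_genes: list[str]
    missing_genes: list[str]
    source_scale_tag: str = "asis"  # "asis" | "minshifted"


def project_signatures(
    expr_new: pd.DataFrame, signatures: SignatureSet
) -> ProjectedDataset:
    """Restrict a new dataset to the discovery signature genes.

    Rows are the matched signature genes in signature order; inputs with
    negative entries (log-ratio microarray scales) are made nonnegative
    by a per-gene minimum shift. Fails when fewer than half the signature
    genes are present.
    """
    sig_genes = signatures.all_genes()
    matched = [g for g in sig_genes if g in expr_new.index]
    missing = [g for g in sig_genes if g not in expr_new.index]
    if len(matched) < 0.5 * len(sig_genes):
        raise ValueError(
            f"only {len(matched)}/{len(sig_genes)} signature genes matched; "
            "projection not meaningful"
        )
    if missing:
        logger.warning("%d signature genes absent from the new dataset", len(missing))
    mat = expr_new.loc[matched].astype(float)
    tag = "asis"
    if (mat.to_numpy() < 0).any():
        mat = mat.sub(mat.min(axis=1).clip(upper=0.0), axis=0)
        tag = "minshifted"
    return ProjectedDataset(
        matrix=mat, matched_genes=matched, missing_genes=missing,
        source_scale_tag=tag,
    )


def cluster_projected(
    proj: ProjectedDataset, config: AnalysisConfig
) -> tuple[dict[int, ConsensusResult], int]:
    """Consensus-NMF the projected matrix over the candidate k values."""
    if proj.matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    results = {
        k: consensus_matrix(
            proj.matrix.to_numpy(), k,
            n_runs=config.n_nmf_runs, base_seed=config.base_seed,
            max_iter=config.max_iter, tol=config.tol,
        )
        for k in config.k_candidates
    }
    return results, select_k(results)


def signature_score_matrix(
    proj: ProjectedDataset, labels: np.ndarray, signatures: SignatureSet
) -> pd.DataFrame:
    """score(cluster, subtype): mean standardized signature expression.

    Each gene is standardized across samples (sd clamped away from 0);
    the score of cluster c for subtype t averages, over c's samples, the
    mean standardized expression of t's matched signature genes.
    """
    labels = np.asarray(labels)
    X = proj.matrix.to_numpy()
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    zdf = pd.DataFrame(Z, index=proj.matrix.index, columns=proj.matrix.columns)

    clusters = sorted(np.unique(labels))
    subtypes = sorted(signatures.genes_by_subtype)
    scores = np.full((len(clusters), len(subtypes)), np.nan)
    for j, t in enumerate(subtypes):
        genes = [g for g in signatures.genes_by_subtype[t].index
                 if g in zdf.index]
        if not genes:
            scores[:, j] = 0.0
            continue
        per_sample = zdf.loc[genes].mean(axis=0).to_numpy()
        for i, c in enumerate(clusters):
            scores[i, j] = per_sample[labels == c].mean()
    return pd.DataFrame(scores, index=clusters, columns=subtypes)


def assign_subtype_identity(
    proj: ProjectedDataset, labels: np.ndarray, signatures: SignatureSet
) -> dict[int, int]:
    """Name each cluster with a discovery subtype.

    One-to-one matching maximizing the total signature score; exact ties
    resolve toward the smaller subtype index (stable assignment order).
    """
    score = signature_score_matrix(proj, labels, signatures)
    if score.shape[0] != score.shape[1]:
        raise ValueError(
            f"cluster/subtype count mismatch: {score.shape[0]} clusters vs "
            f"{score.shape[1]} subtypes"
        )
    row_ind, col_ind = linear_sum_assignment(-score.to_numpy())
    return {
        int(score.index[i]): int(score.columns[j])
        for i, j in zip(row_ind, col_ind)
    }


def plot_signature_heatmap(
    proj: ProjectedDataset,
    labels: np.ndarray,
    signatures: SignatureSet,
    out_path,
) -> None:
    """Standardized signature-gene heatmap, genes and samples grouped.

    Genes are blocked by signature subtype and samples by cluster, with
    annotation bars for both groupings; standardization is display-only.
    """
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    gene_order, gene_groups = [], []
    for t in sorted(signatures.genes_by_subtype):
        genes = [g for g in signatures.genes_by_subtype[t].index
                 if g in proj.matrix.index]
        gene_order.extend(genes)
        gene_groups.extend([t] * len(genes))
    sample_order = np.argsort(labels, kind="stable")

    X = proj.matrix.loc[gene_order].to_numpy()[:, sample_order]
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)

    fig, axes = plt.subplots(
        2, 2, figsize=(8, 6),
        gridspec_kw={"height_ratios": [1, 24], "width_ratios": [1, 24]},
    )
    axes[0, 0].axis("off")
    axes[0, 1].imshow(labels[sample_order][None, :], aspect="auto", cmap="tab10")
    axes[0, 1].set_axis_off()
    axes[1, 0].imshow(np.array(gene_groups)[:, None], aspect="auto", cmap="tab10")
    axes[1, 0].set_axis_off()
    im = axes[1, 1].imshow(
        np.clip(Z, -3, 3), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3
    )
    axes[1, 1].set_xlabel("samples (grouped by cluster)")
    axes[1, 1].set_ylabel("signature genes (grouped by subtype)")
    axes[1, 1].set_xticks([]); axes[1, 1].set_yticks([])
    fig.colorbar(im, ax=axes[1, 1], shrink=0.6, label="z-score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
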