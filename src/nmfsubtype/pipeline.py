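"""End-to-end orchestration: discovery, and transfer to a new cohort.

``discover`` chains normalization, gene selection, per-k consensus NMF,
cophenetic model selection, silhouette core filtering and signature
definition on a count matrix. ``transfer_subtypes`` projects a discovery
signature set onto an independent expression matrix, re-clusters it and
names the clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .consensus import ConsensusResult, consensus_matrix, select_k
from .preprocess import filter_nonexpressed, normalize_cpm, select_by_iqr
from .signatures import (
    SignatureSet,
    assignment_table,
    signatures_from_expression,
    silhouette_scores,
)
from .transfer import (
    ProjectedDataset,
    assign_subtype_identity,
    cluster_projected,
    project_signatures,
    signature_score_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    expression: pd.DataFrame  # selected-gene matrix fed to NMF
    cpm_expressed: pd.DataFrame  # CPM of all expressed genes (DE universe)
    provenance: dict
    consensus: dict[int, ConsensusResult]
    selected_k: int
    assignments: pd.DataFrame  # per-sample label / silhouette / is_core
    signatures: SignatureSet
    de_tables: list[pd.DataFrame] = field(default_factory=list)


@dataclass
class TransferResult:
    projected: ProjectedDataset
    consensus: dict[int, ConsensusResult]
    selected_k: int
    cluster_labels: np.ndarray  # raw cluster indices on the new cohort
    identity_map: dict[int, int]  # cluster -> discovery subtype
    subtype_labels: pd.Series  # per-sample discovery-subtype label
    score_matrix: pd.DataFrame


def discover(
    counts: pd.DataFrame, config: AnalysisConfig, k_override: int | None = None
) -> DiscoveryResult:
    """Run the full discovery pipeline on a raw count matrix."""
    kept = filter_nonexpressed(
        counts, config.cpm_threshold, config.nonexpressed_fraction
    )
    cpm = normalize_cpm(counts).loc[kept]
    X = select_by_iqr(cpm, config.iqr_top_fraction)
    if config.log_expression:
        X = np.log2(X + 1.0)
    provenance = {
        "n_genes_input": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_genes_expressed": int(len(kept)),
        "n_genes_selected": int(X.shape[0]),
        "scale": "log2cpm1" if config.log_expression else "cpm",
        "base_seed": config.base_seed,
    }
    logger.info("discovery on %d genes x %d samples (selected %d genes)",
                *counts.shape, X.shape[0])

    cons = {
        k: consensus_matrix(
            X.to_numpy(), k,
            n_runs=config.n_nmf_runs, base_seed=config.base_seed,
            max_iter=config.max_iter, tol=config.tol,
        )
        for k in config.k_candidates
    }
    k = k_override if k_override is not None else select_k(cons)
    labels = cons[k].consensus_labels

    scores = silhouette_scores(X, labels)
    assignments = assignment_table(list(X.columns), labels, scores)
    core = assignments["is_core"].to_numpy()
    logger.info("selected k=%d; %d/%d core samples", k, core.sum(), len(core))

    sig, de_tables = signatures_from_expression(
        cpm, labels, core, config.fc_cutoff, config.fdr_cutoff
    )
    return DiscoveryResult(
        expression=X, cpm_expressed=cpm, provenance=provenance,
        consensus=cons, selected_k=k, assignments=assignments,
        signatures=sig, de_tables=de_tables,
    )


def transfer_subtypes(
    expr_new: pd.DataFrame,
    signatures: SignatureSet,
    config: AnalysisConfig,
    k_override: int | None = None,
) -> TransferResult:
    """Project discovery signatures onto a new cohort and name its clusters."""
    proj = project_signatures(expr_new, signatures)
    cons, k = cluster_projected(proj, config)
    if k_override is not None:
        k = k_override
    labels = cons[k].consensus_labels
    identity = assign_subtype_identity(proj, labels, signatures)
    score = signature_score_matrix(proj, labels, signatures)
    subtype_labels = pd.Series(
        [identity[int(c)] for c in labels],
        index=proj.matrix.columns, name="subtype",
    )
    return TransferResult(
        projected=proj, consensus=cons, selected_k=k,
        cluster_labels=labels, identity_map=identity,
        subtype_labels=subtype_labels, score_matrix=score,
    )
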