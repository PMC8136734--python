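"""Consensus clustering over repeated NMF runs and cophenetic model selection.

The consensus matrix C averages, over randomly initialized NMF runs, the
binary co-clustering indicator of each sample pair; entry (i, j) estimates
the probability that samples i and j land in the same cluster. Stability
of a candidate k is scored by the cophenetic correlation coefficient
rho_k: the Pearson correlation between the consensus-induced distances
1 - C and the cophenetic distances of their average-linkage dendrogram.
The reported sample labels are the k-group cut of that dendrogram, so the
final clustering is a deterministic function of C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .nmf import assign_clusters, nmf_fit

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    k: int
    C: np.ndarray
    rho: float | None  # None when 1-C has zero variance (undefined)
    consensus_labels: np.ndarray  # 1-based, from the hierarchical cut of 1-C
    run_seeds: list[int] = field(default_factory=list)
    run_labels: np.ndarray | None = None  # n_runs x m argmax labels (diagnostic)
    leaf_order: np.ndarray | None = None  # dendrogram leaf permutation


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary m x m matrix: 1 where two samples share a label."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def run_seed(base_seed: int, k: int, run: int) -> int:
    """Disjoint seed streams per candidate k."""
    return int(base_seed + k * 10**6 + run)


def consensus_matrix(
    A: np.ndarray,
    k: int,
    n_runs: int = 40,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Average the co-clustering indicators of ``n_runs`` seeded NMF fits."""
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    C = np.zeros((m, m))
    seeds, all_labels = [], []
    for r in range(n_runs):
        seed = run_seed(base_seed, k, r)
        try:
            fit = nmf_fit(A, k, seed=seed, max_iter=max_iter, tol=tol)
        except Exception as exc:
            raise RuntimeError(f"NMF run {r} (seed {seed}) failed: {exc}") from exc
        labels = assign_clusters(fit.H)
        C += connectivity_matrix(labels)
        seeds.append(seed)
        all_labels.append(labels)
    C /= n_runs
    np.fill_diagonal(C, 1.0)

    d = squareform(1.0 - C, checks=False)
    Z = linkage(d, method="average")
    consensus_labels = fcluster(Z, t=k, criterion="maxclust")
    rho = cophenetic_coefficient(C)
    logger.info("consensus k=%d over %d runs: rho=%s", k, n_runs,
                "undefined" if rho is None else f"{rho:.4f}")
    return ConsensusResult(
        k=k, C=C, rho=rho,
        consensus_labels=np.asarray(consensus_labels),
        run_seeds=seeds,
        run_labels=np.asarray(all_labels),
        leaf_order=leaves_list(Z),
    )


def cophenetic_coefficient(C: np.ndarray) -> float | None:
    """Pearson correlation between 1-C distances and their dendrogram.

    Computed over the m(m-1)/2 off-diagonal pairs with average linkage.
    Returns None when all pairwise distances are identical (undefined).
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] != C.shape[1] or C.shape[0] < 3:
        raise ValueError("C must be square with m >= 3")
    d = squareform(1.0 - C, checks=False)
    if np.allclose(d, d[0]):
        return None
    Z = linkage(d, method="average")
    rho, _ = cophenet(Z, d)
    return float(rho)


def select_k(results: dict[int, ConsensusResult]) -> int:
    """Smallest candidate k achieving the maximal cophenetic coefficient."""
    if len(results) < 2:
        raise ValueError("need at least 2 candidate k values")
    defined = {k: r.rho for k, r in results.items() if r.rho is not None}
    for k in sorted(set(results) - set(defined)):
        logger.warning("k=%d excluded from selection: undefined rho", k)
    if not defined:
        raise ValueError("no candidate k has a defined cophenetic coefficient")
    best_rho = max(defined.values())
    return min(k for k, rho in defined.items() if rho == best_rho)
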