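"""Divergence-based NMF with Lee-Seung multiplicative updates.

Factorizes a nonnegative expression matrix A (n genes x m samples) as
A ~ W H with W (n x k) and H (k x m) nonnegative, minimizing the
generalized Kullback-Leibler divergence

    D(A || WH) = sum_ij [ A_ij log(A_ij / (WH)_ij) - A_ij + (WH)_ij ].

Each iteration applies the H update then the W update (sequentially, the
W update seeing the fresh H); both are multiplicative, so nonnegativity
is preserved exactly and D is non-increasing. Hard cluster membership of
a sample is the row index of the largest entry in its column of H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FactorPair:
    """Result of one NMF run."""

    W: np.ndarray
    H: np.ndarray
    divergence_trace: list[float] = field(default_factory=list)
    seed: int = 0
    n_iter_run: int = 0
    converged: bool = False


def _clamp(X: np.ndarray, eps: float) -> np.ndarray:
    return np.maximum(X, eps)


def divergence(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(A || WH); 0 log 0 taken as 0."""
    A = np.asarray(A, dtype=float)
    WH = W @ H
    if WH.shape != A.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs WH {WH.shape}")
    eps = np.finfo(float).tiny
    WH = _clamp(WH, eps)
    pos = A > 0
    term = np.zeros_like(A)
    term[pos] = A[pos] * np.log(A[pos] / WH[pos])
    return float(term.sum() - A.sum() + WH.sum())


def nmf_fit(
    A: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorPair:
    """Fit A ~ WH by multiplicative KL updates.

    Stops at ``max_iter`` or when the relative decrease of D over 10
    consecutive iterations falls below ``tol``. Deterministic given
    ``seed`` (uniform random initialization scaled to the matrix mean).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D matrix")
    if (A < 0).any():
        raise ValueError("A must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    if (A.sum(axis=0) == 0).any():
        raise ValueError("A has an all-zero sample column")
    n, m = A.shape

    rng = np.random.default_rng(seed)
    scale = A.mean() / k
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale

    eps = 1e-12 * max(A.max(), 1.0)
    # D = [sum_{A>0} A log A - sum A] - sum A*log(WH) + sum WH; the constant
    # part is A-only, so per iteration only the WH terms are recomputed.
    pos = A > 0
    d_const = float((A[pos] * np.log(A[pos])).sum() - A.sum())
    trace: list[float] = [divergence(A, W, H)]
    WH = _clamp(W @ H, eps)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ (A / WH)) / _clamp(W.sum(axis=0)[:, None], eps)
        WH = _clamp(W @ H, eps)
        W *= ((A / WH) @ H.T) / _clamp(H.sum(axis=1)[None, :], eps)
        WH = _clamp(W @ H, eps)
        d = d_const - float((A * np.log(WH)).sum()) + float(WH.sum())
        if not np.isfinite(d) or not np.isfinite(W).all() or not np.isfinite(H).all():
            raise FloatingPointError(
                "non-finite values during NMF iteration; rescale the input"
            )
        trace.append(d)
        if it >= 10:
            past = trace[-11]
            if past > 0 and (past - d) / past < tol:
                converged = True
                break
            if past == 0.0:
                converged = True
                break
    return FactorPair(
        W=W, H=H, divergence_trace=trace, seed=seed,
        n_iter_run=it, converged=converged,
    )


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """1-based label per sample: argmax over the rows of its H column.

    Ties go to the smallest row index (argmax convention). An all-zero
    column has no defined membership and raises.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be nonnegative")
    if (H.sum(axis=0) == 0).any():
        raise ValueError("all-zero H column: cluster membership undefined")
    return H.argmax(axis=0) + 1
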