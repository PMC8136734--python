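"""Diagnostic figures: consensus heatmaps, the rho curve, silhouette plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .consensus import ConsensusResult


def plot_consensus_heatmap(result: ConsensusResult, out_path) -> None:
    """Consensus matrix reordered by dendrogram leaf order."""
    order = result.leaf_order if result.leaf_order is not None else np.arange(
        result.C.shape[0]
    )
    C = result.C[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(C, vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_title(f"consensus matrix, k={result.k}"
                 + (f" (rho={result.rho:.3f})" if result.rho is not None else ""))
    ax.set_xticks([]); ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_rho_curve(rhos: dict[int, float | None], out_path) -> None:
    """Cophenetic correlation against the candidate number of clusters."""
    ks = sorted(k for k, r in rhos.items() if r is not None)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(ks, [rhos[k] for k in ks], "o-")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("cophenetic correlation")
    ax.set_xticks(ks)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_silhouette(assignments, out_path) -> None:
    """Per-sample silhouette widths, grouped by subtype, sorted within."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    pos = 0
    for label, sub in assignments.groupby("label"):
        vals = np.sort(sub["silhouette"].to_numpy())[::-1]
        ax.bar(np.arange(pos, pos + len(vals)), vals, width=1.0,
               label=f"subtype {label}")
        pos += len(vals) + 3
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("samples")
    ax.set_ylabel("silhouette width")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
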