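"""Core-sample filtering and per-subtype signature genes.

Sample stability is scored by the silhouette width s(i) = (b - a) /
max(a, b), where a is the mean Euclidean distance of sample i to its own
cluster and b the smallest mean distance to any other cluster; samples
with s <= 0 ("outliers") are excluded from downstream analyses. Signature
genes are differentially expressed genes (Welch t-test on log2(CPM+1),
Benjamini-Hochberg FDR) passing linear fold-change and FDR gates, each
assigned to the subtype where its mean core-sample expression is highest.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Per-subtype signature gene lists, ordered by ascending FDR."""

    genes_by_subtype: dict[int, pd.DataFrame]  # columns: log2_fold_change, fdr
    universe: list[str]

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for t in sorted(self.genes_by_subtype):
            out.extend(self.genes_by_subtype[t].index)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.genes_by_subtype):
            df = self.genes_by_subtype[t].copy()
            df["subtype"] = t
            rows.append(df)
        return pd.concat(rows) if rows else pd.DataFrame(
            columns=["log2_fold_change", "fdr", "subtype"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, universe: list[str] | None = None
                   ) -> "SignatureSet":
        by = {
            int(t): sub.drop(columns="subtype")
            for t, sub in df.groupby("subtype", sort=True)
        }
        return cls(genes_by_subtype=by, universe=universe or list(df.index))


def silhouette_scores(X: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Silhouette width per sample over Euclidean distance of X's columns.

    Samples in singleton clusters get s = 0 by convention.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    scores = silhouette_samples(X.to_numpy().T, labels, metric="euclidean")
    return pd.Series(scores, index=X.columns, name="silhouette")


def core_sample_mask(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Core samples are those with strictly positive silhouette width."""
    return np.asarray(scores) > 0


def assignment_table(
    sample_ids: list[str], labels: np.ndarray, scores: pd.Series
) -> pd.DataFrame:
    """Per-sample subtype assignment with silhouette and core flag."""
    return pd.DataFrame(
        {
            "label": np.asarray(labels),
            "silhouette": np.asarray(scores),
            "is_core": core_sample_mask(scores),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def differential_expression(
    X: pd.DataFrame, labels: np.ndarray, pair: tuple[int, int]
) -> pd.DataFrame:
    """Per-gene Welch t-test between two subtypes on log2(CPM+1).

    ``X`` holds CPM values (genes x samples) restricted to core samples;
    ``labels`` are the matching subtype labels. The log2 fold change is
    log2((mean_a + 1) / (mean_b + 1)) on the CPM scale. Degenerate genes
    (zero variance in both groups): p = 1 when the group means coincide,
    else p = 0 with a flag.
    """
    a, b = pair
    labels = np.asarray(labels)
    in_a, in_b = labels == a, labels == b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need at least 2 core samples per subtype")
    Xa = X.to_numpy()[:, in_a]
    Xb = X.to_numpy()[:, in_b]
    La, Lb = np.log2(Xa + 1.0), np.log2(Xb + 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(La, Lb, axis=1, equal_var=False)
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    degenerate = (La.var(axis=1) == 0) & (Lb.var(axis=1) == 0)
    equal_means = np.isclose(La.mean(axis=1), Lb.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    p = np.nan_to_num(p, nan=1.0)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            f"mean_{a}": mean_a,
            f"mean_{b}": mean_b,
            "log2_fold_change": np.log2((mean_a + 1.0) / (mean_b + 1.0)),
            "p_value": p,
            "fdr": fdr,
            "zero_variance": degenerate,
        },
        index=X.index,
    )


def define_signatures(
    de_tables: list[pd.DataFrame],
    X: pd.DataFrame,
    labels: np.ndarray,
    fc_cutoff: float = 1.5,
    fdr_cutoff: float = 0.05,
) -> SignatureSet:
    """Gate DE genes by fold change and FDR and assign each to one subtype.

    A gene passes when |log2FC| >= log2(fc_cutoff) and FDR <= fdr_cutoff
    in any pairwise table; it joins the signature of the subtype where its
    mean CPM over core samples is highest, so the per-subtype lists are
    disjoint by construction. Lists are ordered by ascending (best) FDR.
    """
    labels = np.asarray(labels)
    subtypes = [int(t) for t in np.unique(labels)]
    log_fc_gate = np.log2(fc_cutoff)

    best: dict[str, tuple[float, float]] = {}  # gene -> (best fdr, |log2FC|)
    for de in de_tables:
        hits = de[(de["log2_fold_change"].abs() >= log_fc_gate)
                  & (de["fdr"] <= fdr_cutoff)]
        for gene, row in hits.iterrows():
            prev = best.get(gene)
            if prev is None or row["fdr"] < prev[0]:
                best[gene] = (float(row["fdr"]), float(row["log2_fold_change"]))

    means = {
        t: X.to_numpy()[:, labels == t].mean(axis=1) for t in subtypes
    }
    mean_df = pd.DataFrame(means, index=X.index)

    by_subtype: dict[int, list[tuple[str, float, float]]] = {t: [] for t in subtypes}
    for gene, (fdr, lfc) in best.items():
        up_in = int(mean_df.loc[gene].idxmax())
        by_subtype[up_in].append((gene, lfc, fdr))

    out: dict[int, pd.DataFrame] = {}
    for t in subtypes:
        rows = sorted(by_subtype[t], key=lambda r: (r[2], r[0]))
        out[t] = pd.DataFrame(
            rows, columns=["gene", "log2_fold_change", "fdr"]
        ).set_index("gene")
        if len(rows) == 0:
            logger.warning("empty signature for subtype %d", t)
    return SignatureSet(genes_by_subtype=out, universe=list(X.index))


def signatures_from_expression(
    X: pd.DataFrame,
    labels: np.ndarray,
    core: np.ndarray,
    fc_cutoff: float = 1.5,
    fdr_cutoff: float = 0.05,
) -> tuple[SignatureSet, list[pd.DataFrame]]:
    """Pairwise DE over core samples for every subtype pair, then gating."""
    labels = np.asarray(labels)
    core = np.asarray(core, dtype=bool)
    Xc = X.loc[:, core]
    lc = labels[core]
    pairs = list(itertools.combinations(sorted(int(t) for t in np.unique(lc)), 2))
    de_tables = [differential_expression(Xc, lc, pair) for pair in pairs]
    sig = define_signatures(de_tables, Xc, lc, fc_cutoff, fdr_cutoff)
    return sig, de_tables
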