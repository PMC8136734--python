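"""Subtype-covariate association tests and gene-set over-representation.

Categorical covariates are tested against the subtype labels with
Fisher's exact test, generalized to r x c tables by the Freeman-Halton
probability-ordering rule: the p-value sums the probabilities of all
tables sharing the observed margins whose hypergeometric probability
does not exceed that of the observed table (within the customary
(1 + 1e-7) float tolerance). Small table spaces are enumerated exactly;
large ones fall back to margin-preserving Monte Carlo. Continuous
covariates use the pooled-variance (Student) two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import MetadataTable

logger = logging.getLogger(__name__)

_REL_TOL = 1.0 + 1e-7


@dataclass
class FisherResult:
    p_value: float
    method: str  # "enumeration" | "monte_carlo" | "degenerate"
    n_tables: int | None = None  # tables enumerated
    mc_se: float | None = None  # Monte-Carlo standard error


@dataclass
class AssociationResult:
    variable: str
    test: str  # "fisher_exact" | "t_test" | "skipped"
    p_value: float | None
    n_used: int
    table: pd.DataFrame | None = None  # contingency (categorical)
    group_means: dict[int, float] | None = None  # continuous
    note: str = ""


def _log_table_prob_const(row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    """log[ prod r_i! prod c_j! / N! ] — the cell-independent part."""
    n = row_margins.sum()
    return float(
        gammaln(row_margins + 1).sum() + gammaln(col_margins + 1).sum()
        - gammaln(n + 1)
    )


def _log_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a table given its own margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    return _log_table_prob_const(r, c) - float(gammaln(table + 1).sum())


def _enumerate_rx2(row_margins: np.ndarray, col1: int) -> np.ndarray:
    """Log cell-factorial terms of every r x 2 table with the given margins.

    Vectorized DP over rows; the state is the remaining first-column
    margin, each state carrying the array of partial -sum log(x!) values
    of all branches reaching it.
    """
    states: dict[int, np.ndarray] = {col1: np.zeros(1)}
    suffix = np.concatenate([np.cumsum(row_margins[::-1])[::-1][1:], [0]])
    for r_i, later in zip(row_margins, suffix):
        lg = gammaln(np.arange(r_i + 1) + 1)
        row_terms = -(lg + lg[::-1])  # -log(x!) - log((r_i - x)!) for x=0..r_i
        new: dict[int, list[np.ndarray]] = {}
        for rem, arr in states.items():
            # rem - x must still fit into the later rows' margins
            x_lo, x_hi = max(0, rem - int(later)), min(int(r_i), rem)
            for x in range(x_lo, x_hi + 1):
                new.setdefault(rem - x, []).append(arr + row_terms[x])
        states = {rem: np.concatenate(parts) for rem, parts in new.items()}
    return states.get(0, np.zeros(0))


def _enumerate_general(
    row_margins: np.ndarray, col_margins: np.ndarray
) -> np.ndarray:
    """Depth-first enumeration of -sum log(x_ij!) over all feasible tables."""
    out: list[float] = []
    n_rows = len(row_margins)

    def fill_row(i: int, cols_left: np.ndarray, acc: float) -> None:
        if i == n_rows - 1:
            if cols_left.sum() == row_margins[i]:
                out.append(acc - float(gammaln(cols_left + 1).sum()))
            return
        r_i = row_margins[i]

        def compose(j: int, left: int, part_acc: float) -> None:
            if j == len(cols_left) - 1:
                if left <= cols_left[j]:
                    cols_left[j] -= left
                    fill_row(i + 1, cols_left,
                             part_acc - float(gammaln(left + 1)))
                    cols_left[j] += left
                return
            hi = min(left, cols_left[j])
            for x in range(hi + 1):
                cols_left[j] -= x
                compose(j + 1, left - x, part_acc - float(gammaln(x + 1)))
                cols_left[j] += x

        compose(0, r_i, acc)

    fill_row(0, col_margins.copy(), 0.0)
    return np.asarray(out)


def _count_tables(
    row_margins: np.ndarray, col_margins: np.ndarray, cap: float
) -> float:
    """Exact number of tables with the given margins, by DP over rows on
    the remaining-column-margin state; returns inf once ``cap`` is passed."""
    states: dict[tuple[int, ...], int] = {tuple(int(c) for c in col_margins): 1}
    for r_i in row_margins[:-1]:
        new: dict[tuple[int, ...], int] = {}

        def compose(state: tuple[int, ...], j: int, left: int,
                    acc: list[int], count: int) -> None:
            if j == len(state) - 1:
                if left <= state[j]:
                    key = tuple(acc + [state[j] - left])
                    new[key] = new.get(key, 0) + count
                return
            for x in range(min(left, state[j]) + 1):
                compose(state, j + 1, left - x, acc + [state[j] - x], count)

        for state, count in states.items():
            compose(state, 0, int(r_i), [], count)
        states = new
        if sum(states.values()) > cap * 8:  # early abort on explosive growth
            return float("inf")
    total = sum(
        count for state, count in states.items()
        if sum(state) == int(row_margins[-1])
    )
    return float(total)


def fisher_exact_rxc(
    table: Iterable[Iterable[int]],
    max_tables: float = 1e7,
    n_mc: int = 10**6,
    seed: int = 0,
) -> FisherResult:
    """Freeman-Halton exact test on an r x c contingency table.

    All-zero rows and columns are dropped first (they cannot affect the
    exact test). Exact enumeration when the table-space bound stays under
    ``max_tables``; otherwise margin-preserving Monte Carlo with the
    standard error reported.
    """
    tab = np.asarray(table)
    if not np.issubdtype(tab.dtype, np.integer):
        as_int = np.asarray(table, dtype=float)
        if not np.allclose(as_int, np.round(as_int)):
            raise ValueError("contingency table must hold integer counts")
        tab = np.round(as_int).astype(int)
    if (tab < 0).any():
        raise ValueError("contingency table must be nonnegative")
    nz_rows = tab.sum(axis=1) > 0
    nz_cols = tab.sum(axis=0) > 0
    if (~nz_rows).any() or (~nz_cols).any():
        logger.info("dropping %d all-zero rows and %d all-zero columns",
                    int((~nz_rows).sum()), int((~nz_cols).sum()))
    tab = tab[nz_rows][:, nz_cols]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        logger.warning("degenerate contingency table; p = 1")
        return FisherResult(p_value=1.0, method="degenerate")

    row_m = tab.sum(axis=1)
    col_m = tab.sum(axis=0)
    const = _log_table_prob_const(row_m, col_m)
    lp_obs = const - float(gammaln(tab + 1).sum())
    cut = lp_obs + math.log(_REL_TOL)

    # orient so the short dimension is the columns (cheaper enumeration)
    work = tab if tab.shape[1] <= tab.shape[0] else tab.T
    w_row, w_col = work.sum(axis=1), work.sum(axis=0)

    n_tables = _count_tables(w_row, w_col, max_tables)
    if n_tables <= max_tables:
        if work.shape[1] == 2:
            cell_terms = _enumerate_rx2(w_row, int(w_col[0]))
        else:
            cell_terms = _enumerate_general(w_row, w_col)
        lps = const + cell_terms
        p = float(np.exp(lps[lps <= cut]).sum())
        return FisherResult(
            p_value=min(p, 1.0), method="enumeration", n_tables=len(lps)
        )

    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_m, col_m, seed=rng)
    draws = dist.rvs(n_mc, random_state=rng)
    lps = const - gammaln(draws + 1).sum(axis=(1, 2))
    hits = lps <= cut
    p = float(hits.mean())
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return FisherResult(p_value=p, method="monte_carlo", mc_se=se)


def two_sample_t(
    values: np.ndarray | pd.Series, groups: np.ndarray | pd.Series
) -> tuple[float, dict]:
    """Pooled-variance (Student) two-sided t-test; missing values excluded."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~pd.isna(values) & ~pd.isna(groups)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"two_sample_t needs exactly 2 groups, got {len(levels)}")
    x = values[groups == levels[0]]
    y = values[groups == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 non-missing values per group")
    info = {
        "group_means": {levels[0].item() if hasattr(levels[0], "item") else levels[0]: float(x.mean()),
                        levels[1].item() if hasattr(levels[1], "item") else levels[1]: float(y.mean())},
        "n_used": int(len(x) + len(y)),
    }
    pooled_var = (x.var(ddof=1) * (len(x) - 1) + y.var(ddof=1) * (len(y) - 1))
    if pooled_var == 0.0:
        p = 1.0 if x.mean() == y.mean() else 0.0
        info["zero_variance"] = True
        return p, info
    _, p = stats.ttest_ind(x, y, equal_var=True)
    return float(p), info


def contingency(
    labels: pd.Series, covariate: pd.Series
) -> pd.DataFrame:
    """Covariate-level x subtype count table over non-missing samples."""
    df = pd.DataFrame({"label": labels, "cov": covariate}).dropna()
    return pd.crosstab(df["cov"], df["label"])


def prevalence_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per covariate level, percent of samples in each subtype (1 decimal)."""
    totals = table.sum(axis=1)
    return (table.div(totals, axis=0) * 100).round(1)


def association_report(
    assignments: pd.DataFrame,
    meta: MetadataTable,
    core_only: bool = True,
    mc_seed: int = 0,
) -> list[AssociationResult]:
    """One association test per declared metadata column.

    ``assignments`` is the per-sample table from the signatures stage
    (columns ``label``, ``is_core``). Missing covariate values are
    excluded pairwise per test. Continuous covariates are only testable
    between exactly two subtypes.
    """
    common = assignments.index.intersection(meta.data.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between assignments and metadata")
    sub = assignments.loc[common]
    if core_only and "is_core" in sub.columns:
        sub = sub[sub["is_core"]]
    labels = sub["label"]

    results: list[AssociationResult] = []
    for col, kind in meta.schema.items():
        cov = meta.data.loc[labels.index, col]
        if kind == "categorical":
            tab = contingency(labels, cov)
            observed_levels = tab.index[tab.sum(axis=1) > 0]
            if len(observed_levels) < 2 or tab.shape[1] < 2:
                results.append(AssociationResult(
                    variable=col, test="skipped", p_value=None,
                    n_used=int(tab.to_numpy().sum()), table=tab,
                    note="fewer than 2 observed levels or subtypes",
                ))
                continue
            fr = fisher_exact_rxc(tab.to_numpy(), seed=mc_seed)
            results.append(AssociationResult(
                variable=col, test="fisher_exact", p_value=fr.p_value,
                n_used=int(tab.to_numpy().sum()), table=tab,
                note=fr.method,
            ))
        else:
            n_subtypes = labels.nunique()
            if n_subtypes != 2:
                results.append(AssociationResult(
                    variable=col, test="skipped", p_value=None,
                    n_used=0, note=f"t-test needs 2 subtypes, have {n_subtypes}",
                ))
                continue
            try:
                p, info = two_sample_t(cov.to_numpy(), labels.to_numpy())
            except ValueError as exc:
                results.append(AssociationResult(
                    variable=col, test="skipped", p_value=None, n_used=0,
                    note=str(exc),
                ))
                continue
            results.append(AssociationResult(
                variable=col, test="t_test", p_value=p,
                n_used=info["n_used"], group_means=info["group_means"],
            ))
    return results


def hypergeometric_ora(
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of query vs gene sets.

    For a set with K members in the universe of size N and overlap k with
    the query of size n: p = P(X >= k), fold enrichment = (k/n)/(K/N);
    Benjamini-Hochberg across the tested sets.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        K = len(inset)
        if K == 0:
            continue
        k = len(inset & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((name, k, K, fold, p))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "fold_enrichment", "p_value"]
    ).set_index("set")
    if len(df):
        _, fdr, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["fdr"] = fdr
        df = df.sort_values("p_value")
    else:
        df["fdr"] = []
    return df
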