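# Methods

## Model and procedure

The pipeline treats molecular subtyping as consensus clustering of a
nonnegative expression matrix. A single divergence-based NMF run is a
local optimizer: **A** ≈ **WH** under the generalized Kullback–Leibler
objective D(A‖WH) = Σ(A log(A/WH) − A + WH), minimized by multiplicative
updates (H first, then W with the fresh H, each iteration). Multiplicative
updates preserve nonnegativity exactly and guarantee D is non-increasing;
the tests assert this on every fitted trajectory. A sample's hard cluster
is the argmax row of its **H** column (ties to the smaller index).

Because individual runs depend on initialization, stability is measured
across 40 random restarts per candidate *k*: the consensus matrix **C**
averages binary co-clustering indicators, so entries are exact multiples
of 1/40 in [0, 1], **C** is symmetric and has unit diagonal. The
cophenetic correlation ρ_k is the Pearson correlation over the m(m−1)/2
sample pairs between the distances 1 − C and the cophenetic distances of
their average-linkage dendrogram; ρ_k near 1 means the consensus is
nearly block-binary and hence the clustering is reproducible. The
smallest *k* attaining the maximal ρ_k is selected, and the reported
labels are the *k*-group cut of the same dendrogram — a deterministic
function of **C**, not of any single run (per-run argmax labels are kept
as diagnostics).

Assumptions worth stating: KL-NMF treats entries as Poisson-like
intensities, so the factorized matrix must be nonnegative and roughly
scale-homogeneous (CPM works; per-gene z-scores would not); consensus
stability is evidence of reproducibility under re-initialization, not of
biological truth (see Limitations).

## Parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `cpm_threshold` | 5 | CPM | expression floor for the non-expressed filter |
| `nonexpressed_fraction` | 0.8 | fraction of samples | gene dropped when below threshold in at least this fraction (count rule: `n_below >= fraction*m`, i.e. ≥ ceil when fractional) |
| `iqr_top_fraction` | 0.2 | fraction of genes | keeps `floor(fraction*n)` genes with largest IQR of log2(CPM+1); floor reproduces 2456/1228/4912 from a 12,281-gene pool at 0.2/0.1/0.4 |
| `k_candidates` | 2, 3, 4 | — | cluster numbers scored by ρ_k |
| `n_nmf_runs` | 40 | runs | consensus-matrix sample size per k |
| `max_iter`, `tol` | 2000, 1e-6 | — | stop when the relative D decrease over 10 consecutive iterations < tol |
| `fc_cutoff`, `fdr_cutoff` | 1.5 (linear), 0.05 | — | signature-gene gates |
| `base_seed` | 0 | — | run r at candidate k uses seed `base_seed + k*1e6 + r` (disjoint streams per k) |

## Numerical choices

- **Initialization**: W, H i.i.d. uniform(0,1) scaled by mean(A)/k from a
  per-run seeded generator; identical seeds give bit-identical factors.
- **Zero protection**: (WH) is clamped at 1e-12 × max(A) before division
  and logs; A = 0 entries contribute no log term (0·log 0 := 0).
- **IQR**: quantiles use linear interpolation; selection ties break by
  original gene order (stable sort); output keeps input row order.
- **Silhouette**: Euclidean distance over the same selected-gene matrix
  used for NMF; singleton clusters get s = 0; s = 0 is treated as
  non-core (outlier), a conservative reading of "negative silhouette
  removed".
- **DE**: Welch t-test on log2(CPM+1), log2FC = log2((mean_a+1)/(mean_b+1))
  on the CPM scale, Benjamini–Hochberg across genes. Genes with zero
  variance in both groups: p = 1 when means coincide, else p = 0 with a
  `zero_variance` flag. For k > 2, signatures are the union of all
  pairwise DE runs; every passing gene is assigned to the subtype with
  the highest core-sample mean CPM, making the per-subtype lists disjoint.
- **Freeman–Halton exact test**: two-sided by probability ordering with
  the customary (1 + 1e-7) tolerance (the convention that reproduces
  standard statistical-environment output). The table space is counted
  exactly by dynamic programming over remaining column margins; spaces up
  to 1e7 tables are enumerated (vectorized DP for r×2/2×c after orienting
  the short dimension as columns, feasibility-pruned DFS otherwise),
  larger ones use 1e6 margin-preserving Monte-Carlo draws
  (`scipy.stats.random_table`) with a reported standard error and a fixed
  seed. All-zero rows/columns are dropped first; they cannot change the
  exact p.
- **Transfer identity**: clusters are named by the one-to-one matching
  maximizing the total mean standardized signature score, solved exactly
  with the Hungarian algorithm (`linear_sum_assignment`); with equal
  scores the assignment is stable in subtype order. Negative-valued
  inputs (log-ratio microarray scales) are made nonnegative by per-gene
  min-shift, which preserves within-gene rank order, rather than
  clipping.
- **"Student's t-test"** for continuous covariates is read literally as
  pooled-variance; the DE module independently uses Welch. Missing
  metadata values are excluded pairwise per test.

## Synthetic data: what it emulates and what it does not

`simulate_counts` draws negative-binomial counts (variance
μ + φμ², gamma–Poisson construction) around per-gene lognormal baseline
means (log2-uniform on [1, 8]) times per-sample lognormal library-size
factors (log-sd 0.2), with φ = 0.3 — typical bulk-RNA-seq magnitudes.
Each planted subtype up-regulates a disjoint block of signature genes
multiplicatively by 2^log2FC. The reference conditions used throughout
the tests and the acceptance script are 2000 genes × 200 samples, two
equal subtypes, 100 signature genes each, log2FC 2. Covariates are drawn
conditionally on the true subtype (per-subtype level probabilities or
mean/sd), giving association tests a known ground truth.

Deliberately absent: gene–gene correlation beyond the subtype blocks,
batch effects, cross-platform scale differences, outlier samples, and
subtype structure that is not block-up-regulation. Passing recovery
tests therefore shows the pipeline is a correct implementation that
recovers the structure it assumes, at realistic noise levels — not that
real cohorts contain such structure.

Null-data behaviour deserves emphasis: with no planted structure, the
consensus matrix is *not* dispersed. Random initializations converge to
the same spurious split of the fixed noise realization, yielding
near-binary consensus matrices and ρ_2 ≈ 0.98 on pure-noise cohorts.
This is the well-documented null artifact of consensus clustering — the
procedure measures reproducibility under re-initialization, not evidence
against the null — and it is why a high ρ_k alone should never be read
as proof of subtypes. DE type-I error, association-test and
over-representation p-values on null data are calibrated (checked in the
test suite).

## Design choices where the design was open

- The factorized matrix holds CPM of the selected genes by default;
  log2(CPM+1) is available via `log_expression` and the choice is logged.
  Heatmap z-scoring is display-only and never feeds the factorization.
- Average linkage is used both for ρ_k and for the consensus label cut —
  the standard choice in consensus-NMF practice.
- Final labels come from the consensus hierarchy rather than any single
  NMF run, making the reported clustering deterministic given the seed.
- The DE engine is a Welch t-test behind a narrow interface;
  negative-binomial GLM machinery (edgeR-style dispersion estimation) is
  intentionally out of scope, so discovery-scale signature lists are not
  expected to match counts produced by NB engines gene-for-gene.
- Problem sizes in tests and the acceptance script (reference cohort
  2000 × 200 with 40 runs; null checks at 60 samples with 15 runs;
  Monte-Carlo replicate counts of 100–400) are the package's chosen
  trade-off between statistical resolution and a suite that runs in a
  few minutes on one CPU.

## Known limitations

- KL-NMF multiplicative updates converge slowly near flat optima; the
  10-iteration relative-decrease window can stop early on very flat
  trajectories (tighten `tol` if exact convergence matters).
- The exact r×c test enumerates up to 1e7 tables; beyond that p-values
  are Monte-Carlo with ~1e-3 standard error.
- Transfer assumes the new cohort measures most signature genes (≥ 50 %
  matched) in a comparable identifier namespace; no cross-platform batch
  correction is attempted.
- Association tests are unadjusted (no covariate-controlled regression),
  matching the source analysis design.
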