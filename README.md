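# nmfsubtype

Consensus non-negative matrix factorization (NMF) subtyping of bulk
gene-expression cohorts, with signature-gene transfer to independent
datasets and exact subtype–covariate association tests.

The package is aimed at transcriptomics analysts who have a gene × sample
count matrix for a heterogeneous disease cohort (the motivating use case
is post-mortem brain expression in Alzheimer's disease) and want to ask:
does this cohort decompose into reproducible molecular subtypes, which
genes define them, do the subtypes reappear in an independent cohort, and
are they associated with clinical covariates such as sex, *APOE*
genotype, Braak stage or MMSE?

## Method

Given a nonnegative expression matrix **A** (*n* genes × *m* samples) and
a candidate cluster number *k*, NMF factorizes **A** ≈ **WH** with
**W** (*n* × *k*) and **H** (*k* × *m*) nonnegative, minimizing the
generalized Kullback–Leibler divergence

D(A‖WH) = Σ_ij ( A_ij log ( A_ij / (WH)_ij ) − A_ij + (WH)_ij )

by the Lee–Seung multiplicative updates

H_au ← H_au · Σ_i W_ia A_iu/(WH)_iu / Σ_k W_ka
W_ia ← W_ia · Σ_u H_au A_iu/(WH)_iu / Σ_v H_av

which preserve nonnegativity exactly and never increase D. Each sample's
cluster is the argmax row of its **H** column.

The pipeline around the factorization:

1. **Preprocess** — counts-per-million (CPM) normalization; removal of
   genes with CPM < 5 in ≥ 80 % of samples; retention of the top 20 % of
   genes by interquartile range of log2(CPM+1).
2. **Consensus clustering** — 40 randomly initialized NMF runs per
   candidate *k*; the consensus matrix **C** averages the binary
   co-clustering indicators, so C_ij estimates the probability that
   samples *i, j* cluster together. Model selection maximizes the
   cophenetic correlation ρ_k between the distances 1 − C and the
   cophenetic distances of their average-linkage dendrogram; final labels
   are the *k*-group cut of that dendrogram.
3. **Core samples & signatures** — silhouette width
   s(i) = (b−a)/max(a,b) over Euclidean distances; samples with s ≤ 0
   are dropped. Signature genes pass fold change ≥ 1.5 and
   Benjamini–Hochberg FDR ≤ 0.05 (Welch t-test on log2(CPM+1)) and are
   assigned to the subtype with the highest mean expression.
4. **Transfer** — signature genes are projected onto an independent
   normalized dataset, the projection is consensus-NMF re-clustered, and
   clusters are named by the one-to-one matching that maximizes the mean
   standardized signature score.
5. **Association** — Fisher's exact test for categorical covariates,
   generalized to r × c tables by Freeman–Halton probability ordering
   (exact enumeration, Monte-Carlo fallback for huge table spaces);
   pooled-variance t-test for continuous covariates; hypergeometric
   over-representation for gene sets (GMT).

## Worked example

The `analysis/` scripts run the whole study on synthetic cohorts with
known ground truth (two planted subtypes, 100 up-regulated signature
genes each at log2 fold change 2, in 2000 genes × 200 samples of
negative-binomial counts):

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_discover_subtypes.py
python analysis/03_validate_transfer.py
python analysis/04_test_associations.py
python analysis/05_enrichment_demo.py
```

Output of the discovery step:

```
preprocessing: {'n_genes_input': 2000, 'n_samples': 200, 'n_genes_expressed': 2000,
                'n_genes_selected': 400, 'scale': 'cpm', 'base_seed': 11}
cophenetic rho by k: {2: 1.0, 3: 0.9916, 4: 0.9567}; selected k = 2
core samples (positive silhouette): 200/200
signature genes per subtype: {1: 100, 2: 100}
planted-signature sensitivity at FC 1.5 / FDR 0.05: 1.000
```

ρ_2 = 1.0 means all 40 runs at k = 2 agreed on every sample pair, and ρ
drops for k = 3, 4, so two subtypes are selected; every sample has a
positive silhouette; the FC/FDR gates recover exactly the 100 + 100
planted signature genes. The transfer step then reports

```
matched 200 signature genes (0 missing); selected k = 2; cluster->subtype {1: 1, 2: 2}
named-subtype agreement with simulation truth: 1.000
```

i.e. the independent cohort re-clusters into two groups that are named
correctly for every sample. The association step re-tests the published
discovery-cohort contingency tables with the exact-test engine:

```
published table, sex: p = 0.049 (enumeration)
published table, apoe: p = 0.031 (enumeration)
published table, braak: p = 0.885 (enumeration)
published table, cerad: p = 0.467 (enumeration)
```

A `nmfsubtype` command-line interface exposes the same stages
(`simulate`, `preprocess`, `cluster`, `project`, `associate`, `enrich`);
`nmfsubtype cluster --counts counts.tsv --out out/` runs preprocessing,
consensus clustering, silhouettes and signatures in one call.

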