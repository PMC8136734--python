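"""Analysis configuration: the constants that drive every pipeline stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Pipeline-wide analysis constants.

    Parameters
    ----------
    cpm_threshold
        Counts-per-million level below which a gene is considered not
        expressed in a sample (CPM units).
    nonexpressed_fraction
        A gene is dropped when it is below ``cpm_threshold`` in at least
        this fraction of samples.
    iqr_top_fraction
        Fraction of the filtered genes, ranked by interquartile range of
        log2(CPM+1), retained for factorization.
    k_candidates
        Candidate numbers of subtypes, strictly increasing, each >= 2.
    n_nmf_runs
        Randomly initialized NMF runs aggregated into each consensus matrix.
    max_iter, tol
        Multiplicative-update stopping rule: stop at ``max_iter`` or when
        the relative decrease of the divergence over 10 consecutive
        iterations falls below ``tol``.
    fc_cutoff, fdr_cutoff
        Linear fold-change and Benjamini-Hochberg FDR gates for signature
        genes.
    base_seed
        Root seed; every stochastic stage derives its stream from it.
    log_expression
        When True the factorized matrix holds log2(CPM+1) instead of CPM.
    """

    cpm_threshold: float = 5.0
    nonexpressed_fraction: float = 0.8
    iqr_top_fraction: float = 0.2
    k_candidates: list[int] = field(default_factory=lambda: [2, 3, 4])
    n_nmf_runs: int = 40
    max_iter: int = 2000
    tol: float = 1e-6
    fc_cutoff: float = 1.5
    fdr_cutoff: float = 0.05
    base_seed: int = 0
    log_expression: bool = False

    def __post_init__(self) -> None:
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be >= 0")
        if not 0.0 <= self.nonexpressed_fraction <= 1.0:
            raise ValueError("nonexpressed_fraction must be in [0, 1]")
        if not 0.0 < self.iqr_top_fraction <= 1.0:
            raise ValueError("iqr_top_fraction must be in (0, 1]")
        ks = list(self.k_candidates)
        if len(ks) == 0 or any(k < 2 for k in ks):
            raise ValueError("k_candidates must be integers >= 2")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_candidates must be strictly increasing")
        if self.n_nmf_runs < 1:
            raise ValueError("n_nmf_runs must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.fc_cutoff <= 1.0:
            raise ValueError("fc_cutoff must be > 1")
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError("fdr_cutoff must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
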