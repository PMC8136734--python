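"""Simulate the discovery and validation cohorts used by the analysis.

Two independent 2000-gene x 200-sample cohorts with the same two planted
subtypes (100 signature genes each, log2FC 2), plus per-sample metadata:
sex and a 6-level genotype associated with subtype, and a cognitive score
with a modest subtype shift. Writes counts, truth and metadata TSVs under
results/sim/.
"""

import pathlib

import pandas as pd

from nmfsubtype import io as nio
from nmfsubtype.simulate import (
    CovariateSpec,
    SimulationSpec,
    simulate_counts,
    simulate_metadata,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "sim"

COVARIATES = [
    CovariateSpec(
        name="sex", kind="categorical", levels=["Female", "Male"],
        probs_by_subtype=[[0.6, 0.4], [0.75, 0.25]],
    ),
    CovariateSpec(
        name="genotype", kind="categorical",
        levels=["E2E2", "E2E3", "E2E4", "E3E3", "E3E4", "E4E4"],
        probs_by_subtype=[
            [0.00, 0.11, 0.05, 0.43, 0.40, 0.01],
            [0.01, 0.09, 0.02, 0.61, 0.24, 0.03],
        ],
    ),
    CovariateSpec(
        name="mmse", kind="continuous",
        mean_sd_by_subtype=[(13.8, 7.0), (12.2, 7.0)],
    ),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, seed in [("discovery", 7), ("validation", 8)]:
        spec = SimulationSpec(seed=seed, covariate_specs=COVARIATES)
        counts, truth = simulate_counts(spec)
        nio.write_counts(counts, OUT / f"{name}_counts.tsv")
        pd.DataFrame({
            "true_label": truth.labels, "library_size": truth.library_sizes,
        }).to_csv(OUT / f"{name}_truth.tsv", sep="\t", index_label="sample_id")
        meta = simulate_metadata(truth, COVARIATES)
        nio.write_metadata(meta, OUT / f"{name}_metadata.tsv")
        sig = [(g, t) for t, gs in truth.signature_genes.items() for g in gs]
        pd.DataFrame(sig, columns=["gene", "subtype"]).to_csv(
            OUT / f"{name}_true_signatures.tsv", sep="\t", index=False
        )
        print(f"{name}: {counts.shape[0]} genes x {counts.shape[1]} samples, "
              f"{len(sig)} planted signature genes -> {OUT}")


if __name__ == "__main__":
    main()
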