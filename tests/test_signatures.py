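import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from nmfsubtype.signatures import (
    assignment_table,
    core_sample_mask,
    define_signatures,
    differential_expression,
    signatures_from_expression,
    silhouette_scores,
)


def brute_force_silhouette(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Direct evaluation of s(i) = (b-a)/max(a,b) from pairwise distances."""
    D = cdist(X.T, X.T)
    out = np.zeros(len(labels))
    for i in range(len(labels)):
        own = (labels == labels[i]) & (np.arange(len(labels)) != i)
        if own.sum() == 0:
            out[i] = 0.0  # singleton convention
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == other].mean()
                for other in np.unique(labels) if other != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


def _frame(X):
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(X.shape[1])],
    )


class TestSilhouette:
    def test_one_dimensional_hand_example(self):
        X = _frame(np.array([[0.0, 0.2, 10.0, 10.2]]))
        s = silhouette_scores(X, np.array([1, 1, 2, 2]))
        assert s.iloc[0] == pytest.approx((10.1 - 0.2) / 10.1, abs=1e-12)

    def test_equidistant_sample_scores_zero(self):
        X = _frame(np.array([[0.0, 2.0, -2.0]]))
        s = silhouette_scores(X, np.array([1, 1, 2]))
        assert s.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_mislabeled_sample_scores_negative(self):
        X = _frame(np.array([[0.0, 0.1, 10.0, 10.1, 10.2]]))
        s = silhouette_scores(X, np.array([1, 1, 1, 2, 2]))
        assert s.iloc[2] < 0  # sample at 10 sits with the far cluster

    def test_matches_brute_force_to_1e12(self, rng):
        X = rng.uniform(0, 10, (6, 20))
        labels = rng.integers(1, 4, 20)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(1, 4, 20)
        ours = silhouette_scores(_frame(X), labels).to_numpy()
        ref = brute_force_silhouette(X, labels)
        assert np.allclose(ours, ref, atol=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="at least 2 clusters"):
            silhouette_scores(_frame(np.ones((2, 4))), np.array([1, 1, 1, 1]))


class TestCoreMask:
    def test_sign_rule(self):
        assert core_sample_mask(np.array([0.5, -0.1, 0.3])).tolist() == [
            True, False, True,
        ]
        assert core_sample_mask(np.array([0.0])).tolist() == [False]

    def test_assignment_table_flags_match_scores(self):
        tab = assignment_table(
            ["a", "b"], np.array([1, 2]), pd.Series([0.2, -0.2], index=["a", "b"])
        )
        assert tab.loc["a", "is_core"] and not tab.loc["b", "is_core"]

    def test_planted_mislabels_are_mostly_non_core(self, small_cohort):
        spec, counts, truth = small_cohort
        from nmfsubtype.preprocess import normalize_cpm

        cpm = normalize_cpm(counts)
        labels = truth.labels.to_numpy().copy()
        rng = np.random.default_rng(0)
        flip = rng.choice(len(labels), size=max(1, len(labels) // 20),
                          replace=False)
        labels[flip] = 3 - labels[flip]
        scores = silhouette_scores(cpm, labels)
        non_core = ~core_sample_mask(scores)
        assert non_core[flip].mean() > 0.8


class TestDifferentialExpression:
    def test_identical_groups_gene_has_unit_p_zero_fc(self):
        X = _frame(np.tile([[10.0, 20.0, 30.0, 10.0, 20.0, 30.0]], (3, 1)))
        de = differential_expression(X, np.array([1, 1, 1, 2, 2, 2]), (1, 2))
        assert (de["log2_fold_change"] == 0).all()
        assert (de["p_value"] == 1.0).all()

    def test_constant_unequal_genes_flagged_p_zero(self):
        X = _frame(np.array([[5.0, 5.0, 50.0, 50.0]]))
        de = differential_expression(X, np.array([1, 1, 2, 2]), (1, 2))
        assert de["zero_variance"].all()
        assert (de["p_value"] == 0.0).all()

    def test_planted_signatures_detected_with_high_sensitivity(self, small_cohort):
        spec, counts, truth = small_cohort
        from nmfsubtype.preprocess import normalize_cpm

        cpm = normalize_cpm(counts)
        labels = truth.labels.to_numpy()
        sig, _ = signatures_from_expression(
            cpm, labels, np.ones(len(labels), dtype=bool),
            fc_cutoff=1.5, fdr_cutoff=0.05,
        )
        planted = {g for gs in truth.signature_genes.values() for g in gs}
        detected = set(sig.all_genes())
        assert len(planted & detected) / len(planted) >= 0.9

    def test_null_data_type_one_error_calibrated(self):
        from nmfsubtype.simulate import SimulationSpec, simulate_counts
        from nmfsubtype.preprocess import normalize_cpm

        spec = SimulationSpec(
            n_genes=2000, n_samples=60, n_subtypes=2,
            n_signature_genes_per_subtype=0, seed=17,
        )
        counts, truth = simulate_counts(spec)
        cpm = normalize_cpm(counts)
        de = differential_expression(cpm, truth.labels.to_numpy(), (1, 2))
        assert de["p_value"].lt(0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestDefineSignatures:
    @staticmethod
    def _de(rows):
        return pd.DataFrame(
            rows, columns=["gene", "log2_fold_change", "p_value", "fdr"]
        ).set_index("gene")

    def test_fc_and_fdr_gates(self):
        X = _frame(np.array([
            [20.0, 20.0, 5.0, 5.0],   # up in subtype 1
            [20.0, 20.0, 5.0, 5.0],
            [20.0, 20.0, 5.0, 5.0],
        ]))
        labels = np.array([1, 1, 2, 2])
        de = self._de([
            ("g0", np.log2(1.6), 0.01, 0.04),   # passes both gates
            ("g1", np.log2(1.4), 0.01, 0.04),   # fails FC
            ("g2", np.log2(3.0), 0.02, 0.06),   # fails FDR
        ])
        sig = define_signatures([de], X, labels, fc_cutoff=1.5, fdr_cutoff=0.05)
        assert list(sig.genes_by_subtype[1].index) == ["g0"]
        assert list(sig.genes_by_subtype[2].index) == []

    def test_gene_assigned_to_highest_mean_subtype(self):
        X = _frame(np.array([[5.0, 5.0, 50.0, 50.0]]))
        de = self._de([("g0", -2.0, 0.001, 0.001)])
        sig = define_signatures([de], X, np.array([1, 1, 2, 2]))
        assert list(sig.genes_by_subtype[2].index) == ["g0"]

    def test_subtype_lists_always_disjoint(self, small_cohort):
        spec, counts, truth = small_cohort
        from nmfsubtype.preprocess import normalize_cpm

        cpm = normalize_cpm(counts)
        sig, _ = signatures_from_expression(
            cpm, truth.labels.to_numpy(),
            np.ones(len(truth.labels), dtype=bool),
        )
        lists = [set(df.index) for df in sig.genes_by_subtype.values()]
        assert not (lists[0] & lists[1])

    def test_fdr_gate_is_monotone_in_q(self, small_cohort):
        spec, counts, truth = small_cohort
        from nmfsubtype.preprocess import normalize_cpm

        cpm = normalize_cpm(counts)
        labels = truth.labels.to_numpy()
        core = np.ones(len(labels), dtype=bool)
        small, _ = signatures_from_expression(cpm, labels, core, fdr_cutoff=0.01)
        large, _ = signatures_from_expression(cpm, labels, core, fdr_cutoff=0.10)
        assert set(small.all_genes()) <= set(large.all_genes())
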