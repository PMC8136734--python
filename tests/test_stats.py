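import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from nmfsubtype.io import MetadataTable
from nmfsubtype.stats import (
    association_report,
    contingency,
    fisher_exact_rxc,
    hypergeometric_ora,
    prevalence_table,
    two_sample_t,
)


class TestFisherExact:
    @given(
        st.lists(st.integers(0, 25), min_size=4, max_size=4).filter(
            lambda c: sum(c[:2]) > 0 and sum(c[2:]) > 0
            and c[0] + c[2] > 0 and c[1] + c[3] > 0
        )
    )
    def test_2x2_agrees_with_scipy(self, cells):
        tab = np.array(cells).reshape(2, 2)
        ours = fisher_exact_rxc(tab).p_value
        ref = sps.fisher_exact(tab).pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_row_and_column_permutation_invariance(self, rng):
        tab = rng.integers(0, 15, (3, 3))
        tab[0, 0] += 1
        p = fisher_exact_rxc(tab).p_value
        rp = rng.permutation(3)
        cp = rng.permutation(3)
        assert fisher_exact_rxc(tab[np.ix_(rp, cp)]).p_value == pytest.approx(
            p, abs=1e-10
        )
        assert fisher_exact_rxc(tab.T).p_value == pytest.approx(p, abs=1e-10)

    def test_zero_row_does_not_change_p(self):
        with_zero = [[0, 0], [5, 4], [101, 87]]
        without = [[5, 4], [101, 87]]
        assert fisher_exact_rxc(with_zero).p_value == pytest.approx(
            fisher_exact_rxc(without).p_value, abs=1e-12
        )

    def test_degenerate_single_row_is_unit_p(self):
        res = fisher_exact_rxc([[3, 4, 5]])
        assert res.p_value == 1.0 and res.method == "degenerate"

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact_rxc([[1.5, 2], [3, 4]])

    def test_enumeration_agrees_with_monte_carlo(self, rng):
        for _ in range(3):
            tab = rng.integers(0, 11, (3, 2))
            tab += 1  # avoid degenerate margins
            exact = fisher_exact_rxc(tab)
            assert exact.method == "enumeration"
            mc = fisher_exact_rxc(tab, max_tables=0, n_mc=200_000, seed=4)
            assert mc.method == "monte_carlo"
            assert abs(exact.p_value - mc.p_value) <= 3 * mc.mc_se + 1e-9

    def test_monte_carlo_deterministic_given_seed(self):
        tab = [[8, 3], [2, 9], [5, 5]]
        p1 = fisher_exact_rxc(tab, max_tables=0, n_mc=50_000, seed=7).p_value
        p2 = fisher_exact_rxc(tab, max_tables=0, n_mc=50_000, seed=7).p_value
        assert p1 == p2


class TestTwoSampleT:
    def test_identical_groups_give_unit_p(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array([1, 1, 1, 2, 2, 2])
        p, info = two_sample_t(vals, groups)
        assert p == pytest.approx(1.0)
        assert info["group_means"] == {1: 2.0, 2: 2.0}

    def test_missing_values_excluded_pairwise(self):
        vals = np.array([1.0, 2.0, np.nan, 10.0, 11.0, 12.0])
        groups = np.array([1, 1, 1, 2, 2, 2])
        p, info = two_sample_t(vals, groups)
        assert info["n_used"] == 5
        assert p < 0.01

    def test_zero_variance_conventions(self):
        p_eq, _ = two_sample_t(np.array([5.0, 5, 5, 5]), np.array([1, 1, 2, 2]))
        assert p_eq == 1.0
        p_ne, info = two_sample_t(np.array([5.0, 5, 9, 9]), np.array([1, 1, 2, 2]))
        assert p_ne == 0.0 and info.get("zero_variance")

    def test_power_matches_closed_form_at_one_sd_shift(self):
        """Shift of 1 pooled SD at n=50/group: Monte-Carlo rejection rate at
        alpha=0.05 matches the noncentral-t power."""
        n = 50
        df = 2 * n - 2
        nc = 1.0 / np.sqrt(2.0 / n)
        tcrit = sps.t.ppf(0.975, df)
        power = 1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(0, 1, n)
            y = rng.normal(1, 1, n)
            p, _ = two_sample_t(
                np.concatenate([x, y]),
                np.repeat([1, 2], n),
            )
            rejections += p < 0.05
        se = np.sqrt(power * (1 - power) / n_rep)
        assert abs(rejections / n_rep - power) <= 4 * se


class TestAssociationReport:
    @staticmethod
    def _inputs():
        idx = [f"s{i}" for i in range(12)]
        assign = pd.DataFrame(
            {
                "label": [1] * 6 + [2] * 6,
                "silhouette": [0.5] * 11 + [-0.2],
                "is_core": [True] * 11 + [False],
            },
            index=pd.Index(idx, name="sample_id"),
        )
        meta = MetadataTable(
            data=pd.DataFrame(
                {
                    "sex": pd.Categorical(["F"] * 5 + ["M"] * 7),
                    "mmse": np.r_[np.arange(6) + 20.0, np.arange(6) + 10.0],
                    "site": pd.Categorical(["x"] * 12),
                },
                index=pd.Index(idx, name="sample_id"),
            ),
            schema={"sex": "categorical", "mmse": "continuous",
                    "site": "categorical"},
        )
        return assign, meta

    def test_core_only_and_per_column_tests(self):
        assign, meta = self._inputs()
        results = {r.variable: r for r in association_report(assign, meta)}
        assert results["sex"].test == "fisher_exact"
        assert results["sex"].n_used == 11  # non-core sample excluded
        assert results["mmse"].test == "t_test"
        assert results["mmse"].p_value < 0.05
        assert results["site"].test == "skipped"  # single level

    def test_prevalence_arithmetic(self):
        tab = pd.DataFrame([[37, 23]], index=["Male"], columns=[1, 2])
        prev = prevalence_table(tab)
        assert prev.loc["Male", 1] == 61.7
        tab2 = pd.DataFrame([[10, 4]], index=["Male"], columns=[1, 2])
        assert prevalence_table(tab2).loc["Male", 1] == 71.4

    def test_contingency_drops_missing_pairwise(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        cov = pd.Series(["F", None, "F", "M"], index=list("abcd"))
        tab = contingency(labels, cov)
        assert tab.to_numpy().sum() == 3

    def test_no_overlap_rejected(self):
        assign, meta = self._inputs()
        assign.index = [f"z{i}" for i in range(12)]
        with pytest.raises(ValueError, match="no overlapping"):
            association_report(assign, meta)


class TestHypergeometricOra:
    def test_fold_enrichment_formula(self):
        universe = [f"g{i}" for i in range(500)]
        sets = {"S": universe[:10]}
        query = universe[:5] + universe[100:145]  # n=50, overlap k=5
        res = hypergeometric_ora(query, universe, sets)
        assert res.loc["S", "fold_enrichment"] == pytest.approx(5.0)
        assert res.loc["S", "overlap"] == 5

    def test_query_equals_universe_is_null(self):
        universe = [f"g{i}" for i in range(40)]
        res = hypergeometric_ora(universe, universe, {"S": universe[:7]})
        assert res.loc["S", "fold_enrichment"] == pytest.approx(1.0)
        assert res.loc["S", "p_value"] == pytest.approx(1.0)

    def test_random_queries_give_uniform_p(self, rng):
        universe = [f"g{i}" for i in range(300)]
        sets = {"S": universe[:30]}
        ps = []
        for _ in range(300):
            query = list(rng.choice(universe, size=50, replace=False))
            ps.append(hypergeometric_ora(query, universe, sets).loc["S", "p_value"])
        # discrete p-values: check super-uniformity of rejection rate instead
        assert np.mean(np.array(ps) < 0.05) <= 0.08

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_ora(["x"], ["a", "b"], {"S": ["a"]})
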