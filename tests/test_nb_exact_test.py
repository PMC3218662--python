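import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import countde as cd
from countde.nb_exact_test import NBParams


def brute_force_pvalue(kA: int, kB: int, pA: NBParams, pB: NBParams) -> float:
    """Literal enumeration oracle: direct pmf products and the <= rule.

    Mathematically exact ties between splits occur for rational NB
    parameters (the pmf ratio products cancel analytically); a 1e-9
    relative guard keeps float round-off from dropping them.  Distinct
    non-tied terms differ by far more on this scale.
    """
    ks = kA + kB
    a = np.arange(ks + 1)
    pa = np.exp(pA.logpmf(a))
    pb = np.exp(pB.logpmf(ks - a))
    pr = pa * pb
    obs = pr[kA]
    return float(pr[pr <= obs * (1 + 1e-9)].sum() / pr.sum())


def _pmf_direct(p: NBParams, k):
    if p.is_poisson:
        return stats.poisson.pmf(k, p.mean)
    r = p.size
    return stats.nbinom.pmf(k, r, r / (r + p.mean))


PARAM_PAIRS = [
    (NBParams(10.0, 30.0), NBParams(10.0, 30.0)),    # symmetric NB
    (NBParams(5.0, 40.0), NBParams(15.0, 60.0)),     # asymmetric NB
    (NBParams(8.0, 8.0), NBParams(8.0, 8.0)),        # Poisson limit
    (NBParams(3.0, 12.0), NBParams(20.0, 20.0)),     # NB vs Poisson
]


class TestNBParams:
    def test_moment_matched_size(self):
        p = NBParams.from_moments(20.0, 30.0)
        assert p.size == pytest.approx(400.0 / 10.0)
        assert not p.is_poisson

    def test_poisson_fallback_when_variance_at_most_mean(self):
        assert NBParams.from_moments(10.0, 10.0).is_poisson
        assert NBParams.from_moments(10.0, 7.0).is_poisson
        assert np.isinf(NBParams.from_moments(10.0, 9.0).size)

    def test_degenerate_zero_mean(self):
        p = NBParams.from_moments(0.0, 0.0)
        assert p.is_degenerate
        np.testing.assert_array_equal(p.logpmf([0, 1, 2]),
                                      [0.0, -np.inf, -np.inf])

    @pytest.mark.parametrize("p", [NBParams(10.0, 30.0), NBParams(4.0, 4.0),
                                   NBParams(200.0, 900.0)])
    def test_pmf_sums_to_one(self, p):
        support = np.arange(0, int(p.mean + 60 * np.sqrt(p.variance)) + 1)
        total = np.exp(p.logpmf(support)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_logpmf_range_recurrence_matches_scipy(self):
        """The fast cumulative-recurrence path (used above the full-
        enumeration cutoff) agrees with scipy's gammaln-based logpmf."""
        for p in (NBParams(5000.0, 2e6), NBParams(9000.0, 9000.0)):
            full = p.logpmf_range(12_000)   # recurrence path
            ref = p.logpmf(np.arange(12_001))
            np.testing.assert_allclose(full, ref, rtol=0, atol=1e-8)


class TestExactPvalue:
    def test_total_zero(self):
        p = NBParams(5.0, 15.0)
        assert cd.exact_pvalue(0, 0, p, p) == 1.0

    def test_most_probable_split_gives_one(self):
        p = NBParams(10.0, 30.0)
        ks = 20
        a = np.arange(ks + 1)
        pr = _pmf_direct(p, a) * _pmf_direct(p, ks - a)
        amax = int(np.argmax(pr))
        assert cd.exact_pvalue(amax, ks - amax, p, p) == pytest.approx(1.0)

    @pytest.mark.parametrize("pA,pB", PARAM_PAIRS)
    def test_matches_brute_force_enumeration(self, pA, pB):
        for ks in (1, 2, 7, 20, 61):
            for kA in range(0, ks + 1, max(1, ks // 7)):
                got = cd.exact_pvalue(kA, ks - kA, pA, pB)
                want = brute_force_pvalue(kA, ks - kA, pA, pB)
                assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry_for_equal_margins(self):
        p = NBParams(6.0, 24.0)
        for kA, kB in [(0, 9), (3, 6), (2, 14)]:
            assert cd.exact_pvalue(kA, kB, p, p) == pytest.approx(
                cd.exact_pvalue(kB, kA, p, p), rel=1e-12)

    def test_super_uniform_under_exact_null(self):
        """Conditional validity: P(p <= alpha) <= alpha (up to discreteness)
        when the data really come from the test's model."""
        rng = np.random.default_rng(0)
        pA = NBParams(12.0, 36.0)
        r = pA.size
        draws_a = rng.negative_binomial(r, r / (r + pA.mean), 3000)
        draws_b = rng.negative_binomial(r, r / (r + pA.mean), 3000)
        pvals = np.array([cd.exact_pvalue(int(a), int(b), pA, pA)
                          for a, b in zip(draws_a, draws_b)])
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = (pvals <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / pvals.size)
            assert frac <= alpha + 3 * se

    def test_point_mass_at_one_for_low_counts(self):
        rng = np.random.default_rng(1)
        p = NBParams(2.0, 6.0)
        r = p.size
        draws = rng.negative_binomial(r, r / (r + p.mean), (500, 2))
        pvals = [cd.exact_pvalue(int(a), int(b), p, p) for a, b in draws]
        assert np.mean(np.asarray(pvals) == 1.0) > 0.05


class TestPooledMeanAndSumParams:
    def test_pooled_mean_unit_factors(self):
        sf = pd.Series([1.0] * 4, index=list("abcd"))
        assert cd.pooled_mean([4, 6, 5, 5], sf, list("abcd")) == 5.0

    def test_pooled_mean_zero(self):
        sf = pd.Series([1.0, 2.0], index=["a", "b"])
        assert cd.pooled_mean([0, 0], sf, ["a", "b"]) == 0.0

    def test_pooled_mean_scaled(self):
        sf = pd.Series([2.0, 2.0], index=["a", "b"])
        assert cd.pooled_mean([8, 12], sf, ["a", "b"]) == 5.0

    def test_sum_params_poisson_marker(self, null_pipeline):
        vf = null_pipeline["vfs"]["A"]

        class ZeroVF:
            def raw_variance(self, q):
                return np.zeros_like(np.asarray(q, dtype=float))

        p = cd.condition_sum_params(5.0, np.array([1.0, 1.0]), ZeroVF())
        assert p.mean == 10.0 and p.is_poisson

    def test_sum_params_moment_arithmetic(self):
        class ConstVF:
            def raw_variance(self, q):
                return np.full_like(np.asarray(q, dtype=float), 5.0)

        p = cd.condition_sum_params(10.0, np.array([1.0, 1.0]), ConstVF())
        assert p.mean == 20.0
        assert p.variance == 30.0
        assert p.size == pytest.approx(40.0)

    def test_zero_pooled_mean_degenerate(self, null_pipeline):
        p = cd.condition_sum_params(0.0, np.array([1.0, 1.0]),
                                    null_pipeline["vfs"]["A"])
        assert p.is_degenerate


class TestAdjustBH:
    def test_all_ones(self):
        np.testing.assert_array_equal(cd.adjust_bh([1.0, 1.0, 1.0]),
                                      [1.0, 1.0, 1.0])

    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(cd.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert cd.adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cd.adjust_bh([0.5, 1.5])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_literal_stepup_rule(self, pvals):
        """Independent oracle: literal BH step-up computed by hand."""
        p = np.asarray(pvals)
        n = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(cd.adjust_bh(p), adj, rtol=1e-12)


class TestTestTwoConditions:
    def test_self_comparison_all_p_one(self, worked_counts):
        counts = pd.concat(
            [worked_counts, worked_counts.set_axis(["s3", "s4"], axis=1)],
            axis=1)
        design = cd.Design.from_labels(counts.columns, ["A", "A", "B", "B"])
        sf = cd.estimate_size_factors(counts)

        class ZeroVF:
            bias_coefficient = 0.0

            def raw_variance(self, q):
                return np.zeros_like(np.asarray(q, dtype=float))

        vfs = {"A": ZeroVF(), "B": ZeroVF()}
        res = cd.test_two_conditions(counts, design, sf, vfs, "A", "B")
        np.testing.assert_array_equal(res["pval"], 1.0)
        np.testing.assert_array_equal(res["padj"], 1.0)
        np.testing.assert_allclose(res["foldChange"], 1.0)

    def test_result_table_contracts(self, null_pipeline):
        np_ = null_pipeline
        res = cd.test_two_conditions(np_["counts"], np_["design"], np_["sf"],
                                     np_["vfs"], "A", "B")
        assert ((res["pval"] >= 0) & (res["pval"] <= 1)).all()
        assert ((res["padj"] >= 0) & (res["padj"] <= 1)).all()
        assert (res["padj"] >= res["pval"] - 1e-12).all()
        np.testing.assert_allclose(res["padj"],
                                   cd.adjust_bh(res["pval"].to_numpy()))

    def test_infinite_fold_change_with_finite_p(self, null_pipeline):
        np_ = null_pipeline
        counts = np_["counts"].copy()
        gene = counts.index[0]
        counts.loc[gene, ["A_1", "A_2"]] = 0
        counts.loc[gene, ["B_1", "B_2"]] = [500, 480]
        res = cd.test_two_conditions(counts, np_["design"], np_["sf"],
                                     np_["vfs"], "A", "B")
        assert np.isposinf(res.loc[gene, "log2FoldChange"])
        assert 0.0 <= res.loc[gene, "pval"] < 0.01

    def test_all_zero_gene_gets_p_one_and_undefined_fold(self, null_pipeline):
        np_ = null_pipeline
        counts = np_["counts"].copy()
        gene = counts.index[1]
        counts.loc[gene] = 0
        res = cd.test_two_conditions(counts, np_["design"], np_["sf"],
                                     np_["vfs"], "A", "B")
        assert res.loc[gene, "pval"] == 1.0
        assert np.isnan(res.loc[gene, "foldChange"])

    def test_results_tsv_roundtrip(self, tmp_path, null_pipeline):
        np_ = null_pipeline
        res = cd.test_two_conditions(np_["counts"].head(50), np_["design"],
                                     np_["sf"], np_["vfs"], "A", "B")
        res.iloc[0, res.columns.get_loc("foldChange")] = np.inf
        res.iloc[0, res.columns.get_loc("log2FoldChange")] = np.inf
        res.iloc[1, res.columns.get_loc("foldChange")] = np.nan
        path = tmp_path / "res.tsv"
        cd.write_results(res, path)
        text = path.read_text()
        assert "Inf" in text and "NA" in text
        back = cd.read_results(path)
        np.testing.assert_allclose(back["pval"], res["pval"], rtol=1e-6)
        assert np.isposinf(back["foldChange"].iloc[0])
        assert np.isnan(back["foldChange"].iloc[1])
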