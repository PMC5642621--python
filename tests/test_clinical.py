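import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats

from seednet.clinical import (
    cox_score_chisq,
    covariate_tests,
    logrank_chisq,
    pairwise_correlation,
    risk_score,
    stratify_and_test,
)
from seednet.synthetic import simulate_clinical
from seednet.types import SeednetError


def expr_frame(rows, samples=None):
    genes = list(rows)
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i}" for i in range(n)]
    return pd.DataFrame([rows[g] for g in genes], index=genes, columns=samples, dtype=float)


class TestPairwiseCorrelation:
    def test_identical_vectors_give_r_one_with_floored_p(self):
        e = expr_frame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10]})
        [st] = pairwise_correlation(e, [("a", "b")])
        assert st.statistic == pytest.approx(1.0)
        assert 0 < st.p <= 1e-8

    def test_zero_correlation_gives_p_one(self):
        # orthogonalized pair: r is exactly 0 by construction
        x = np.arange(10, dtype=float)
        x -= x.mean()
        y = np.zeros(10)
        y[: len(y) // 2] = 1.0
        y -= y.mean()
        y -= (y @ x) / (x @ x) * x
        e = expr_frame({"a": list(x), "b": list(y)})
        [st] = pairwise_correlation(e, [("a", "b")])
        assert abs(st.statistic) < 1e-12
        assert st.p == pytest.approx(1.0, abs=1e-9)

    def test_p_matches_closed_form_t_transform(self):
        # build a pair with r ~ 0.6 at n = 30 and verify the t tail
        rng = np.random.default_rng(4)
        n = 30
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * z
        e = expr_frame({"a": list(x), "b": list(y)})
        [st] = pairwise_correlation(e, [("a", "b")])
        r = st.statistic
        t = r * np.sqrt((n - 2) / (1 - r * r))
        expected_p = 2 * stats.t.sf(abs(t), df=n - 2)
        assert st.p == pytest.approx(expected_p, abs=1e-9)

    def test_bh_adjustment_appended_across_pairs(self):
        rng = np.random.default_rng(12)
        e = expr_frame({g: list(rng.standard_normal(15)) for g in "abcd"})
        res = pairwise_correlation(e, [("a", "b"), ("a", "c"), ("b", "d")])
        raw = [st.p for st in res]
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(raw, method="fdr_bh")[1]
        assert [st.p_adj for st in res] == pytest.approx(list(expected))

    def test_constant_gene_flagged_without_p(self):
        e = expr_frame({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4]})
        [st] = pairwise_correlation(e, [("a", "b")])
        assert np.isnan(st.statistic) and np.isnan(st.p)

    def test_pairwise_complete_samples_used(self):
        e = expr_frame({"a": [1, 2, 3, 4, np.nan], "b": [2, 4, 6, 8, 100]})
        [st] = pairwise_correlation(e, [("a", "b")])
        assert st.n == 4
        assert st.statistic == pytest.approx(1.0)


class TestCovariateTests:
    def clinical_with(self, values, samples):
        return pd.DataFrame({"gender": values}, index=pd.Index(samples, name="sample"))

    def test_identical_groups_give_t_zero_p_one(self):
        samples = [f"s{i}" for i in range(8)]
        e = expr_frame({"g": [1, 2, 3, 4, 1, 2, 3, 4]}, samples)
        clin = self.clinical_with(["m"] * 4 + ["f"] * 4, samples)
        [st] = covariate_tests(e, clin, ["g"], "gender")
        assert st.statistic == pytest.approx(0.0, abs=1e-12)
        assert st.p == pytest.approx(1.0)

    def test_ten_sd_shift_is_detected(self):
        samples = [f"s{i}" for i in range(10)]
        base = [0.0, 0.1, -0.1, 0.05, -0.05]
        e = expr_frame({"g": base + [x + 10 for x in base]}, samples)
        clin = self.clinical_with(["m"] * 5 + ["f"] * 5, samples)
        [st] = covariate_tests(e, clin, ["g"], "gender")
        assert st.p < 1e-4

    def test_matches_textbook_welch_formula(self):
        samples = [f"s{i}" for i in range(9)]
        g1 = np.array([1.1, 2.3, 0.7, 1.9])
        g2 = np.array([3.0, 2.8, 4.1, 3.3, 2.5])
        e = expr_frame({"g": list(g1) + list(g2)}, samples)
        clin = self.clinical_with(["a"] * 4 + ["b"] * 5, samples)
        [st] = covariate_tests(e, clin, ["g"], "gender")
        se = np.sqrt(g1.var(ddof=1) / 4 + g2.var(ddof=1) / 5)
        t_hand = (g1.mean() - g2.mean()) / se
        assert st.statistic == pytest.approx(t_hand, abs=1e-9)

    def test_missing_covariate_dropped_and_small_group_skipped(self):
        samples = [f"s{i}" for i in range(6)]
        e = expr_frame({"g": [1, 2, 3, 4, 5, 6]}, samples)
        clin = self.clinical_with(["m", "m", "m", "f", np.nan, np.nan], samples)
        assert covariate_tests(e, clin, ["g"], "gender") == []

    def test_three_level_covariate_rejected(self):
        samples = [f"s{i}" for i in range(6)]
        e = expr_frame({"g": [1, 2, 3, 4, 5, 6]}, samples)
        clin = self.clinical_with(["a", "a", "b", "b", "c", "c"], samples)
        with pytest.raises(SeednetError, match="levels"):
            covariate_tests(e, clin, ["g"], "gender")


class TestRiskScore:
    def test_two_gene_signature_sums_values(self):
        e = expr_frame({"a": [1.0, 0.0], "b": [2.5, 0.0]}, ["s1", "s2"])
        scores = risk_score(e, ["a", "b"])
        assert scores["s1"] == pytest.approx(3.5)

    def test_all_zero_expression_gives_zero_scores(self):
        e = expr_frame({"a": [0, 0, 0], "b": [0, 0, 0]})
        assert (risk_score(e, ["a", "b"]) == 0).all()

    def test_matches_column_sum_oracle(self):
        rng = np.random.default_rng(6)
        e = expr_frame({f"g{i}": list(rng.standard_normal(8)) for i in range(6)})
        scores = risk_score(e, list(e.index))
        expected = e.to_numpy().sum(axis=0)
        assert scores.to_numpy() == pytest.approx(expected)

    def test_absent_signature_gene_named_in_error(self):
        e = expr_frame({"a": [1, 2, 3]})
        with pytest.raises(SeednetError, match="zz"):
            risk_score(e, ["a", "zz"])

    def test_missing_values_excluded_from_sum(self):
        e = expr_frame({"a": [1.0, np.nan], "b": [2.0, 5.0]}, ["s1", "s2"])
        scores = risk_score(e, ["a", "b"])
        assert scores["s2"] == pytest.approx(5.0)


def toy_cohort(rng, n=60, hr=1.0, missing=0):
    ids = [f"P{i:03d}" for i in range(n)]
    scores = pd.Series(rng.standard_normal(n), index=ids)
    high = (scores > scores.median()).to_numpy()
    clin = simulate_clinical(ids, high, hr, 0.25, missing / n, rng)
    return scores, clin


class TestStratifyAndTest:
    def test_sixteen_missing_of_179_retains_163(self):
        rng = np.random.default_rng(0)
        scores, clin = toy_cohort(rng, n=179, hr=1.0, missing=16)
        strat = stratify_and_test(scores, clin)
        assert strat.n_retained == 163
        assert strat.n_excluded == 16

    def test_identical_group_survival_gives_p_one(self):
        # two groups with literally the same times and events
        times = [5.0, 8.0, 12.0, 20.0]
        ids = [f"P{i}" for i in range(8)]
        clin = pd.DataFrame(
            {"os_days": times + times, "event": [1, 1, 0, 1] * 2},
            index=pd.Index(ids, name="sample"),
        )
        scores = pd.Series([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0], index=ids)
        strat = stratify_and_test(scores, clin)
        assert strat.logrank_chisq == pytest.approx(0.0, abs=1e-9)
        assert strat.logrank_p == pytest.approx(1.0)

    def test_median_split_balanced_with_ties_to_low(self):
        rng = np.random.default_rng(3)
        scores, clin = toy_cohort(rng, n=101)
        strat = stratify_and_test(scores, clin)
        n_low = sum(1 for v in strat.labels.values() if v == "low")
        n_high = sum(1 for v in strat.labels.values() if v == "high")
        assert abs(n_low - n_high) <= 1
        # the sample exactly at the odd-length median lands in the low group
        at_median = [s for s, v in scores.items() if v == strat.threshold]
        for s in at_median:
            assert strat.labels[s] == "low"

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        scores, clin = toy_cohort(rng, n=80, hr=2.0)
        a = stratify_and_test(scores, clin)
        b = stratify_and_test(np.exp(scores * 3), clin)
        assert a.labels == b.labels
        assert a.logrank_chisq == pytest.approx(b.logrank_chisq, abs=1e-12)

    def test_km_curves_start_at_one_and_never_increase(self):
        rng = np.random.default_rng(7)
        scores, clin = toy_cohort(rng, n=70, hr=2.5)
        strat = stratify_and_test(scores, clin)
        for curve in strat.km_curves.values():
            probs = [p for _, p in curve]
            assert probs[0] == pytest.approx(1.0)
            assert all(b <= a + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_chisq_agrees_with_lifelines_and_cox_score(self):
        rng = np.random.default_rng(9)
        for hr in (1.0, 2.0, 4.0):
            scores, clin = toy_cohort(rng, n=90, hr=hr)
            strat = stratify_and_test(scores, clin)
            kept = clin["os_days"].notna() & clin["event"].notna()
            time = clin.loc[kept, "os_days"].to_numpy(float)
            event = clin.loc[kept, "event"].to_numpy(int)
            grp = np.array(
                [1 if strat.labels[s] == "high" else 0 for s in clin.index[kept]]
            )
            ll = lifelines_logrank(
                time[grp == 0], time[grp == 1], event[grp == 0], event[grp == 1]
            )
            assert strat.logrank_chisq == pytest.approx(ll.test_statistic, abs=1e-6)
            # continuous survival times -> no ties -> score test identical
            assert strat.logrank_chisq == pytest.approx(
                cox_score_chisq(time, event, grp), abs=1e-6
            )

    def test_all_scores_tied_is_a_reported_error(self):
        ids = [f"P{i}" for i in range(10)]
        clin = pd.DataFrame(
            {"os_days": np.linspace(5, 50, 10), "event": [1] * 10},
            index=pd.Index(ids, name="sample"),
        )
        scores = pd.Series(np.ones(10), index=ids)
        with pytest.raises(SeednetError, match="median"):
            stratify_and_test(scores, clin)
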