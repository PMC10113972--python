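import math

import numpy as np
import pytest
from scipy import integrate, stats

from lungquant.cohort_stats import (
    SummaryStat,
    age_adjust_residuals,
    analyze_cohort,
    binormal_auc,
    chi_square_2x2,
    fisher_exact_2x2,
    mann_whitney,
    proportion_percent,
    roc_empirical,
    welch_t_data,
    welch_t_summary,
)
from lungquant.cohort_synth import CohortConfig, simulate_cohort
from lungquant.errors import DomainError

# printed group summaries used repeatedly below
PNEUMONIA_RATIO = SummaryStat(33.04, 11.4, 28)
NO_PNEUMONIA_RATIO = SummaryStat(18.3, 8.5, 45)


class TestSummaryStat:
    def test_from_data(self):
        s = SummaryStat.from_data([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.n == 3

    @pytest.mark.parametrize("kwargs", [dict(mean=0, sd=1, n=1), dict(mean=0, sd=0, n=5)])
    def test_validation(self, kwargs):
        with pytest.raises(DomainError):
            SummaryStat(**kwargs)


class TestWelch:
    def test_identical_summaries(self):
        s = SummaryStat(5.0, 2.0, 10)
        r = welch_t_summary(s, s)
        assert r.statistic == 0.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_contusion_row_significant(self):
        r = welch_t_summary(PNEUMONIA_RATIO, NO_PNEUMONIA_RATIO)
        assert r.p_two_sided < 0.0001

    def test_p_matches_quadrature_oracle(self):
        a = SummaryStat(1.0, 1.0, 10)
        b = SummaryStat(0.0, 1.0, 10)
        r = welch_t_summary(a, b)

        # independent oracle: integrate the t density at the computed df
        def t_pdf(x, df):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(lambda x: t_pdf(x, r.df), abs(r.statistic), np.inf)
        assert r.p_two_sided == pytest.approx(2 * tail, rel=1e-8)

    def test_data_equals_summary_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            from_data = welch_t_data(x, y)
            from_summary = welch_t_summary(SummaryStat.from_data(x), SummaryStat.from_data(y))
            assert from_data.statistic == pytest.approx(from_summary.statistic)
            assert from_data.p_two_sided == pytest.approx(from_summary.p_two_sided)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 20), rng.normal(0.7, 2, 15)
        r = welch_t_data(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert r.statistic == pytest.approx(t)
        assert r.p_two_sided == pytest.approx(p)
        rp = welch_t_data(x, y, pooled=True)
        tp, pp = stats.ttest_ind(x, y, equal_var=True)
        assert rp.statistic == pytest.approx(tp)
        assert rp.p_two_sided == pytest.approx(pp)


class TestMannWhitney:
    def test_identical_multisets(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p_two_sided == pytest.approx(1.0)

    def test_tiny_exact_case(self):
        # all C(4,2)=6 arrangements enumerated: P(U=0)=1/6 each tail -> 1/3
        r = mann_whitney([1, 2], [3, 4])
        assert r.method == "mann_whitney_exact"
        assert r.p_two_sided == pytest.approx(1 / 3)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.permutation(100)[: rng.integers(2, 8)].astype(float)
            y = rng.permutation(100)[20 : 20 + rng.integers(2, 8)].astype(float)
            if np.intersect1d(x, y).size:
                continue
            ours = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        ours = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.method == "mann_whitney_normal"
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_input(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_balanced_table(self):
        r = chi_square_2x2([[10, 10], [10, 10]])
        assert r.statistic == 0.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_pneumonia_table_significant(self):
        r = chi_square_2x2([[5, 30], [23, 15]])
        assert r.p_two_sided < 0.005

    def test_textbook_four_term_loop(self):
        table = [[7, 12], [18, 5]]
        r = chi_square_2x2(table)
        # independent oracle: explicit sum of (O-E)^2/E over the four cells
        t = np.array(table, float)
        n = t.sum()
        chi2 = 0.0
        for i in range(2):
            for j in range(2):
                e = t[i].sum() * t[:, j].sum() / n
                chi2 += (t[i, j] - e) ** 2 / e
        assert r.statistic == pytest.approx(chi2)

    def test_yates_matches_scipy(self):
        table = [[5, 30], [23, 15]]
        r = chi_square_2x2(table, yates=True)
        ref = stats.chi2_contingency(np.array(table), correction=True)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DomainError):
            chi_square_2x2([[0, 0], [5, 10]])

    def test_non_integer_rejected(self):
        with pytest.raises(DomainError):
            chi_square_2x2([[1.5, 2], [3, 4]])


class TestFisher:
    def test_ards_table_matches_enumeration_oracle(self):
        # margins fixed at r1=35, r2=38, c1=5: six admissible tables
        table = [[0, 35], [5, 33]]
        r = fisher_exact_2x2(table)
        n, r1, c1 = 73, 35, 5
        probs = {}
        for k in range(0, 6):  # k = top-left cell
            probs[k] = (
                math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
            )
        p_obs = probs[0]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))
        assert r.p_two_sided == pytest.approx(expected, rel=1e-10)

    def test_completeness(self):
        # hypergeometric probabilities over all admissible tables sum to 1
        n, r1, c1 = 73, 35, 5
        total = sum(
            math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
            for k in range(0, min(r1, c1) + 1)
        )
        assert total == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("table", [[[0, 35], [5, 33]], [[5, 30], [23, 15]],
                                       [[2, 3], [4, 1]], [[0, 2], [0, 5]]])
    def test_matches_scipy(self, table):
        r = fisher_exact_2x2(table)
        _, p = stats.fisher_exact(np.array(table), alternative="two-sided")
        assert r.p_two_sided == pytest.approx(p, rel=1e-9)


class TestRoc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [False, False, False, True, True, True]
        r = roc_empirical(scores, labels)
        assert r.auc == pytest.approx(1.0)
        assert r.sens_at_youden == pytest.approx(1.0)
        assert r.spec_at_youden == pytest.approx(1.0)

    def test_constant_score(self):
        r = roc_empirical([5.0] * 10, [True] * 4 + [False] * 6)
        assert r.auc == pytest.approx(0.5)

    def test_auc_equals_pairwise_count_oracle(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(0, 8, 20).astype(float)  # deliberate ties
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc_empirical(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert r.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_auc_equals_trapezoid_of_stored_curve(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(0, 1, 60)
        labels = rng.random(60) < 0.4
        r = roc_empirical(scores, labels)
        fpr = np.concatenate([[0.0], (1.0 - r.specificity)[::-1]])
        tpr = np.concatenate([[0.0], r.sensitivity[::-1]])
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(14)
        r = roc_empirical(rng.normal(0, 1, 50), rng.random(50) < 0.5)
        assert (np.diff(r.sensitivity) <= 1e-12).all()

    def test_youden_tie_breaks_to_smallest_threshold(self):
        # two thresholds achieve the same Youden index; expect the smaller
        r = roc_empirical([1, 2, 3, 4], [False, False, True, True])
        assert r.youden_threshold == 3.0

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_empirical([1, 2, 3], [True, True, True])


class TestBinormal:
    def test_equal_means(self):
        assert binormal_auc((5, 2), (5, 3)) == pytest.approx(0.5)

    def test_printed_contusion_parameters(self):
        auc = binormal_auc(PNEUMONIA_RATIO, NO_PNEUMONIA_RATIO)
        assert round(auc, 2) == 0.85

    def test_huge_gap(self):
        assert binormal_auc((10, 1), (0, 1)) > 0.9999

    def test_agrees_with_empirical_at_scale(self):
        rng = np.random.default_rng(15)
        n = 50_000
        scores = np.concatenate([rng.normal(1.0, 1.5, n), rng.normal(0.0, 1.0, n)])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        emp = roc_empirical(scores, labels).auc
        closed = binormal_auc((1.0, 1.5), (0.0, 1.0))
        assert emp == pytest.approx(closed, abs=0.01)


class TestAgeAdjust:
    def test_exactly_linear_score(self):
        age = np.linspace(20, 80, 40)
        score = 0.5 * age + 3
        group = np.array(["a", "b"] * 20)
        out = age_adjust_residuals(score, age, group)
        assert np.allclose(out["residuals"], 0, atol=1e-9)
        for s in out["groups"].values():
            assert s.mean == pytest.approx(0.0, abs=1e-9)

    def test_pooled_residuals_sum_to_zero(self):
        rng = np.random.default_rng(16)
        age = rng.uniform(18, 90, 200)
        score = rng.normal(30, 10, 200)
        group = np.where(rng.random(200) < 0.5, "m", "s")
        out = age_adjust_residuals(score, age, group)
        assert out["residuals"].sum() == pytest.approx(0.0, abs=1e-6)

    def test_slope_recovery(self):
        rng = np.random.default_rng(17)
        n = 10_000
        age = rng.uniform(18, 90, n)
        group = np.where(rng.random(n) < 0.5, "m", "s")
        score = 0.4 * age + rng.normal(0, 5, n)
        out = age_adjust_residuals(score, age, group)
        assert out["slope"] == pytest.approx(0.4, abs=0.05)

    def test_constant_age_singular(self):
        with pytest.raises(DomainError):
            age_adjust_residuals([1, 2, 3, 4], [50, 50, 50, 50], ["a", "a", "b", "b"])

    def test_requires_two_groups(self):
        with pytest.raises(DomainError):
            age_adjust_residuals([1, 2, 3], [40, 50, 60], ["a", "a", "a"])


class TestProportion:
    @pytest.mark.parametrize("count,expected", [(28, 38.4), (5, 6.8), (2, 2.7)])
    def test_printed_cohort_percentages(self, count, expected):
        assert proportion_percent(count, 73) == expected

    def test_invalid(self):
        with pytest.raises(DomainError):
            proportion_percent(5, 0)


class TestAnalyzeCohort:
    def test_default_cohort_report_structure(self):
        table = simulate_cohort(CohortConfig(n=73, seed=31))
        report = analyze_cohort(table)
        assert report["n"] == 73
        assert set(report["outcome_percent"]) == {"pneumonia", "ards", "mortality"}
        assert "welch" in report["by_pneumonia"]["contusion_ratio"]
        assert "roc_contusion_ratio_vs_pneumonia" in report
        roc = report["roc_contusion_ratio_vs_pneumonia"]
        assert roc["normal_lung_percent_threshold"] == pytest.approx(
            100.0 - roc["youden_threshold"], abs=0.005
        )
        assert "age_adjusted_contusion_ratio" in report

    def test_outcome_percent_matches_counts(self):
        table = simulate_cohort(CohortConfig(n=73, seed=32))
        report = analyze_cohort(table)
        assert report["outcome_percent"]["pneumonia"] == proportion_percent(
            int(table["pneumonia"].sum()), 73
        )
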