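"""Cronbach's alpha, Feldt intervals, and subdomain-total correlation checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import proval as pv


class TestCronbachAlpha:
    def test_hand_computed_example(self):
        # item variances 1 and 1, total variance 3 -> alpha = 2*(1 - 2/3) = 2/3
        res = pv.cronbach_alpha([[1, 2], [2, 1], [3, 3]])
        assert res.alpha == pytest.approx(2 / 3)
        assert res.k == 2 and res.n == 3

    def test_perfectly_correlated_components(self):
        x = np.arange(10.0)
        res = pv.cronbach_alpha(np.column_stack([x, x]))
        assert res.alpha == pytest.approx(1.0)

    def test_single_component_flagged(self):
        res = pv.cronbach_alpha(np.arange(5.0).reshape(-1, 1))
        assert not res.defined and res.flag == "single_component"
        assert res.alpha is None

    def test_zero_total_variance_flagged(self):
        res = pv.cronbach_alpha([[1, 1], [1, 1], [1, 1]])
        assert res.flag == "zero_total_variance"

    def test_insufficient_cases_flagged(self):
        res = pv.cronbach_alpha([[1, 2], [2, 1]])
        assert res.flag == "insufficient_cases"

    def test_listwise_deletion(self):
        mat = np.array([[1, 2], [2, 1], [3, 3], [np.nan, 4]])
        res = pv.cronbach_alpha(mat)
        assert res.n == 3
        assert res.alpha == pytest.approx(2 / 3)

    def test_shift_and_joint_scale_invariance(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(40, 6)) + rng.normal(size=(40, 1))
        a0 = pv.cronbach_alpha(mat).alpha
        assert pv.cronbach_alpha(mat + 7.5).alpha == pytest.approx(a0)
        assert pv.cronbach_alpha(mat * 3.2).alpha == pytest.approx(a0)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        mat = rng.normal(size=(60, 5)) + 0.8 * rng.normal(size=(60, 1))
        res = pv.cronbach_alpha(mat)
        a_pg, ci_pg = pingouin.cronbach_alpha(data=pd.DataFrame(mat))
        assert res.alpha == pytest.approx(a_pg, abs=1e-10)
        assert res.ci_low == pytest.approx(ci_pg[0], abs=0.01)
        assert res.ci_high == pytest.approx(ci_pg[1], abs=0.01)


class TestFeldtInterval:
    def test_perfect_alpha_degenerate_interval(self):
        lo, hi = pv.alpha_confidence_interval(1.0, n=50, k=5)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_textbook_f_quantile_oracle(self):
        # independently coded Feldt bounds for alpha=0.8, n=100, k=10
        alpha, n, k = 0.8, 100, 10
        df1, df2 = n - 1, (n - 1) * (k - 1)
        expect_lo = 1 - (1 - alpha) * stats.f.ppf(0.975, df1, df2)
        expect_hi = 1 - (1 - alpha) * stats.f.ppf(0.025, df1, df2)
        lo, hi = pv.alpha_confidence_interval(alpha, n, k)
        assert lo == pytest.approx(expect_lo)
        assert hi == pytest.approx(expect_hi)
        assert lo < alpha < hi

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pv.alpha_confidence_interval(0.8, n=2, k=5)

    def test_coverage_on_exchangeable_items(self):
        """95% Feldt interval covers the population alpha ~95% of the time."""
        k, rho, n, reps = 5, 0.5, 200, 1000
        true_alpha = k * rho / (1 + (k - 1) * rho)
        rng = np.random.default_rng(99)
        covered = 0
        for _ in range(reps):
            common = rng.standard_normal((n, 1))
            mat = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal((n, k))
            res = pv.cronbach_alpha(mat)
            covered += res.ci_low <= true_alpha <= res.ci_high
        assert 0.92 <= covered / reps <= 0.975


class TestSpearmanBrownRecovery:
    def test_estimated_alpha_matches_closed_form(self):
        k, rho, n = 5, 0.5, 2000
        target = k * rho / (1 + (k - 1) * rho)  # 0.8333
        mat = pv.generate_item_matrix(n, k, rho, seed=21)
        assert pv.cronbach_alpha(mat).alpha == pytest.approx(target, abs=0.02)

    def test_zero_rho_gives_zero_alpha(self):
        mat = pv.generate_item_matrix(5000, 5, 0.0, seed=22)
        assert pv.cronbach_alpha(mat).alpha == pytest.approx(0.0, abs=0.05)

    def test_high_rho_approaches_one(self):
        mat = pv.generate_item_matrix(500, 4, 0.99, seed=23)
        assert pv.cronbach_alpha(mat).alpha > 0.98


class TestReliabilityTable:
    def test_single_question_domain_not_calculable(self, cohort):
        rel = pv.reliability_table(cohort)
        fears = rel[rel.component == "fears"]
        assert (fears.flag == "single_component").all()
        assert fears.alpha.isna().all()

    def test_three_scopes_present(self, cohort):
        rel = pv.reliability_table(cohort)
        assert set(rel.scope) == {"baseline", "followup", "telephone"}
        tot = rel[(rel.component == "total") & (rel.scope == "baseline")].iloc[0]
        assert 0 < tot.alpha <= 1
        assert tot.ci_low <= tot.alpha <= tot.ci_high

    def test_question_level_components_option(self, cohort):
        rel = pv.reliability_table(cohort, total_components="questions")
        tot = rel[(rel.component == "total") & (rel.scope == "baseline")].iloc[0]
        assert tot.k == 22


class TestSubdomainCorrelations:
    def test_self_identical_to_total(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        sc = pd.DataFrame({"a": x, "b": rng.normal(size=100)})
        rows = pv.subdomain_total_correlations(sc, total=pd.Series(x))
        row = rows[rows.subdomain == "a"].iloc[0]
        assert row.r_with_total == pytest.approx(1.0)

    def test_independent_subdomain_near_zero(self):
        rng = np.random.default_rng(4)
        n = 1000
        sc = pd.DataFrame({f"d{i}": rng.normal(size=n) for i in range(5)})
        rows = pv.subdomain_total_correlations(sc)
        row = rows[rows.subdomain == "d0"].iloc[0]
        assert abs(row.r_excluding_self) < 0.1

    def test_excluding_self_attenuates(self, big_cohort):
        """For every domain of a correlated cohort, r with the total (which
        contains the domain) exceeds r with the leave-one-out mean."""
        ds = pv.score_domains(big_cohort)
        base = ds.scores.xs("baseline", level="visit")
        total = pv.score_total(ds).xs("baseline", level="visit")
        rows = pv.subdomain_total_correlations(base, total)
        assert (rows.r_with_total >= rows.r_excluding_self - 1e-9).all()

    def test_zero_variance_flagged(self):
        sc = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]})
        rows = pv.subdomain_total_correlations(sc)
        assert rows[rows.subdomain == "a"].flag.iloc[0] == "degenerate"
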