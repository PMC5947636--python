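"""Descriptive battery: contingency tests, rank tests, Friedman analysis,
post hocs and change summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from jdmsm.descriptive import (
    bonferroni_threshold,
    change_summary,
    friedman_test,
    rank_sum_test,
    signed_rank_posthoc,
    signed_rank_test,
    two_by_two_test,
)
from jdmsm.errors import InsufficientDataError, ValidationError

from _oracles import (
    fisher_oracle,
    friedman_permutation_oracle,
    rank_sum_enumeration_oracle,
    signed_rank_sign_flip_oracle,
)


class TestTwoByTwo:
    def test_balanced_table_is_null(self):
        res = two_by_two_test(10, 10, 10, 10)
        assert res.statistic == 0 and res.p_value == 1

    def test_zero_margin_chi2_errors_fisher_p1(self):
        with pytest.raises(ValidationError):
            two_by_two_test(0, 0, 5, 5)
        assert two_by_two_test(0, 0, 5, 5, method="fisher").p_value == 1

    def test_fisher_small_table_exact(self):
        # full hypergeometric enumeration over x in {0,1,2} gives 1/3
        assert two_by_two_test(2, 0, 0, 2, method="fisher").p_value == pytest.approx(1 / 3)

    def test_relabeling_invariance(self):
        for method in ("chi2_cc", "fisher"):
            p0 = two_by_two_test(21, 35, 21, 123, method=method).p_value
            p_rows = two_by_two_test(21, 123, 21, 35, method=method).p_value
            p_cols = two_by_two_test(35, 21, 123, 21, method=method).p_value
            assert p0 == pytest.approx(p_rows) == pytest.approx(p_cols)

    def test_fisher_matches_enumeration_spot(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            p = two_by_two_test(a, b, c, d, method="fisher").p_value
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_chi2_cc_close_to_conditional_null(self):
        """The continuity-corrected chi-square p approximates the exact
        conditional (hypergeometric) p of the same statistic; checked by
        10^6-draw Monte Carlo on two mid-sized tables."""
        rng = np.random.default_rng(4)
        for (a, b, c, d) in [(21, 35, 21, 123), (36, 20, 68, 76)]:
            res = two_by_two_test(a, b, c, d)
            n, r1, c1 = a + b + c + d, a + b, a + c
            draws = rng.hypergeometric(r1, n - r1, c1, size=1_000_000)
            bb = r1 - draws
            cc = c1 - draws
            dd = n - r1 - cc
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = (
                    n
                    * np.maximum(np.abs(draws * dd - bb * cc) - n / 2, 0) ** 2
                    / (r1 * (n - r1) * c1 * (n - c1))
                )
            p_mc = float((stat >= res.statistic - 1e-9).mean())
            assert p_mc == pytest.approx(res.p_value, abs=0.005)


class TestRankSum:
    def test_separated_samples_exact(self):
        # all 20 assignments enumerated; only the two extremes qualify
        assert rank_sum_test([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_all_tied(self):
        assert rank_sum_test([5, 5, 5, 5, 5, 5], [5, 5, 5, 5, 5, 5]).p_value == 1.0

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.integers(0, 4, size=rng.integers(2, 5)).astype(float)
            y = rng.integers(0, 4, size=rng.integers(2, 5)).astype(float)
            if np.unique(np.concatenate([x, y])).size == 1:
                continue
            assert rank_sum_test(x, y).p_value == pytest.approx(
                rank_sum_enumeration_oracle(x, y)
            )

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        ps = [rank_sum_test(x, x + s).p_value for s in (0.2, 0.6, 1.0, 1.6)]
        assert ps == sorted(ps, reverse=True)


class TestSignedRank:
    def test_three_positive_differences(self):
        # 2 of the 8 sign patterns are as extreme: p = 0.25
        assert signed_rank_test([1, 2, 3]).p_value == pytest.approx(0.25)

    def test_symmetric_differences(self):
        assert signed_rank_test([-1, 1, -2, 2]).p_value == 1.0

    def test_all_zero_differences(self):
        res = signed_rank_test([0.0, 0.0])
        assert res.p_value == 1.0 and res.n_used == 0

    def test_exact_matches_sign_flip_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.integers(-4, 5, size=rng.integers(2, 9)).astype(float)
            if (d == 0).all():
                continue
            assert signed_rank_test(d).p_value == pytest.approx(
                signed_rank_sign_flip_oracle(d)
            )

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, size=40)
        ours = signed_rank_test(d).p_value
        ref = stats.wilcoxon(d, mode="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestFriedman:
    def test_constant_blocks_degenerate(self):
        res = friedman_test(np.ones((4, 3)))
        assert res.statistic == 0 and res.p_value == 1

    def test_perfectly_ordered_blocks(self):
        res = friedman_test([[1, 2, 3]] * 3)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0498, abs=2e-4)

    def test_matches_scipy_on_random_matrix(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(12, 4))
        ours = friedman_test(mat)
        ref = stats.friedmanchisquare(*mat.T)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(4, 3))
        ours = friedman_test(mat, method="exact")
        assert ours.p_value == pytest.approx(friedman_permutation_oracle(mat))

    def test_too_few_blocks(self):
        with pytest.raises(InsufficientDataError):
            friedman_test([[1, 2, 3]])

    def test_incomplete_cases_rejected(self):
        m = np.ones((3, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValidationError):
            friedman_test(m)


class TestBonferroni:
    def test_published_thresholds(self):
        # 14 baseline comparisons -> 0.05/14 ~ 0.0036; 12 medication rows -> 0.0042
        assert bonferroni_threshold(0.05, 14) == pytest.approx(0.003571, abs=5e-7)
        assert round(bonferroni_threshold(0.05, 14), 4) == 0.0036
        assert bonferroni_threshold(0.05, 12) == pytest.approx(0.004167, abs=5e-7)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_posthoc_threshold_for_six_pairs(self):
        wide = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 4)),
                            columns=[0, 6, 12, 24])
        table = signed_rank_posthoc(wide, alpha=0.05)
        assert len(table) == 6
        assert table["threshold"].unique() == pytest.approx(0.05 / 6)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)


class TestChangeSummary:
    def test_planted_improvement_monotone(self):
        """With a clear improvement trend plus the planted late treatment
        effect, treated patients' skin score declines monotonically across
        0/6/12/24 months after CYC start and the muscle score rises."""
        from jdmsm.simulate import SimulationConfig, simulate_cohort

        cohort, _ = simulate_cohort(SimulationConfig(seed=21, trend_slope=0.05))
        das = change_summary(cohort, "das").table
        assert das["median"].is_monotonic_decreasing
        cmas = change_summary(cohort, "cmas").table
        assert cmas["median"].is_monotonic_increasing

    def test_default_cohort_improves_by_two_years(self, sim_cohort):
        """Under the default (linear, shallow) improvement trend the medians
        still fall clearly once the late treatment effect kicks in."""
        cohort, _ = sim_cohort
        med = change_summary(cohort, "das").table["median"]
        assert med.iloc[3] < med.iloc[2] < med.iloc[1]
        assert med.iloc[3] < med.iloc[0] - 1.0

    def test_missing_fractions_reflect_planted_rates(self, sim_cohort):
        cohort, _ = sim_cohort
        summ = change_summary(cohort, "pga")
        # nominal-window misses add to item missingness, so rates are >= planted
        assert (summ.table["missing_frac"] >= 0.10).all()
        assert (summ.table["missing_frac"] <= 0.45).all()

    def test_constant_measure_constant_medians(self):
        from conftest import make_cohort

        c = make_cohort(
            {
                "A": dict(visits=[0, 1, 6.5, 13, 25.5], cyc=(1.0, 6.0)),
                "B": dict(visits=[0, 1.5, 7.5, 13.5, 25.0], cyc=(1.5, 7.0)),
            }
        )
        summ = change_summary(c, "das")
        assert summ.table["median"].nunique() == 1

    def test_feeds_friedman(self, sim_cohort):
        cohort, _ = sim_cohort
        blocks = change_summary(cohort, "das").complete_blocks
        res = friedman_test(blocks)
        assert res.p_value < 0.01  # planted improvement is detected
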