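"""Unit and property tests for the statistical kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from biofilmkit.stats import (
    ComparisonResult,
    ContingencyTable,
    SampleGroup,
    dunnett_critical_value,
    dunnett_many_to_one,
    dunnett_max_abs_cdf,
    enumerate_table_probabilities,
    fisher_exact_rxc,
    iqr_filter,
    shapiro_wilk,
    tukey_all_pairs,
    welch_anova,
    welch_t,
)


class TestIqrFilter:
    @pytest.mark.parametrize(
        "values, expected_removed",
        [
            ([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], [100.0]),  # Q1=3.25, Q3=7.75, fence 14.5
            ([5, 5, 5, 5], []),  # IQR 0, all at the median
            ([1, 2, 3, 4], []),  # fences -2.0 and 7.0
        ],
    )
    def test_fence_examples(self, values, expected_removed):
        kept, removed = iqr_filter(values)
        assert removed == expected_removed
        assert sorted(kept + removed) == sorted(float(v) for v in values)

    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError):
            iqr_filter([1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=4, max_size=40)
    )
    def test_partition_property(self, values):
        kept, removed = iqr_filter(values)
        assert len(kept) + len(removed) == len(values)
        q1, q3 = np.percentile(values, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert all(lo <= v <= hi for v in kept)
        assert all(v < lo or v > hi for v in removed)

    def test_single_pass_not_iterated(self):
        # after removing the extreme point, refiltering the survivors can
        # remove more; the filter itself must not do that implicitly
        values = [1, 1.1, 1.2, 1.3, 3.0, 50.0]
        kept, removed = iqr_filter(values)
        assert removed == [50.0]
        kept2, removed2 = iqr_filter(kept)
        assert removed2 == [3.0]  # only an explicit second pass removes it


class TestWelchAnova:
    def test_two_groups_reduce_to_welch_t(self):
        a, b = [1.0, 2.0, 3.0, 4.5], [2.0, 3.0, 5.0, 9.0, 4.0]
        res = welch_anova([SampleGroup("a", a), SampleGroup("b", b)])
        _, _, p_t = welch_t(a, b)
        assert res.p == pytest.approx(p_t, abs=1e-12)
        assert res.df1 == 1

    def test_extreme_separation(self):
        res = welch_anova(
            [SampleGroup("lo", (0.0, 0.1, -0.1)), SampleGroup("hi", (10.0, 10.1, 9.9))]
        )
        assert res.p < 1e-3

    def test_zero_variance_group_named(self):
        with pytest.raises(ValueError, match="flat"):
            welch_anova([SampleGroup("flat", (1.0, 1.0, 1.0)), SampleGroup("b", (1.0, 2.0, 3.0))])

    def test_null_rejection_rate(self):
        # identically-distributed groups: rejection rate ~ alpha
        rng = np.random.default_rng(20260927)
        rejections = 0
        n_sim = 10_000
        for _ in range(n_sim):
            groups = [SampleGroup(f"g{i}", tuple(rng.normal(0, 1, 8))) for i in range(3)]
            rejections += welch_anova(groups).p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.01)


class TestWelchT:
    def test_closed_form_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)

    def test_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert t == 0.0
        assert p == 1.0

    def test_both_constant_equal(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_one_constant_sample(self):
        t, df, p = welch_t([2.0, 2.0, 2.0], [1.0, 3.0, 5.0])
        assert math.isfinite(t) and 0 <= p <= 1

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=10),
        st.lists(st.floats(-100, 100), min_size=2, max_size=10),
    )
    def test_antisymmetry(self, a, b):
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2, rel=1e-12, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 2, 9)
        t, df, p = welch_t(a, b)
        ref = ss.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self):
        groups = [SampleGroup("c", (1.0, 2.0, 3.0, 4.0)), SampleGroup("t", (2.0, 3.0, 5.0, 9.0))]
        res = dunnett_many_to_one(groups, "c")
        ref = ss.ttest_ind([2, 3, 5, 9], [1, 2, 3, 4], equal_var=True)
        assert res[0].p_adjusted == pytest.approx(ref.pvalue, abs=1e-6)

    def test_extreme_separation_positive(self):
        rng = np.random.default_rng(0)
        groups = [
            SampleGroup("control", tuple(rng.normal(1.0, 0.05, 8))),
            SampleGroup("treat", tuple(rng.normal(2.0, 0.05, 8))),
        ]
        res = dunnett_many_to_one(groups, "control")
        assert res[0].significant and res[0].direction == "positive"

    def test_missing_control_refused(self):
        with pytest.raises(ValueError, match="control"):
            dunnett_many_to_one([SampleGroup("a", (1.0, 2.0)), SampleGroup("b", (1.0, 3.0))], "c")

    def test_matches_scipy_unbalanced(self):
        rng = np.random.default_rng(11)
        groups = [SampleGroup(f"g{i}", tuple(rng.normal(0.2 * i, 1, 5 + i))) for i in range(5)]
        mine = dunnett_many_to_one(groups, "g0")
        ref = ss.dunnett(
            *[np.array(g.values) for g in groups[1:]], control=np.array(groups[0].values)
        )
        for r, p in zip(mine, ref.pvalue):
            assert r.p_adjusted == pytest.approx(p, abs=5e-4)

    def test_adjusted_exceeds_unadjusted(self):
        rng = np.random.default_rng(5)
        groups = [SampleGroup(f"g{i}", tuple(rng.normal(0, 1, 6))) for i in range(4)]
        s2 = sum((g.n - 1) * g.var for g in groups) / (sum(g.n for g in groups) - 4)
        for r in dunnett_many_to_one(groups, "g0"):
            t = abs(r.estimate) / math.sqrt(s2 * (1 / 6 + 1 / 6))
            p_raw = 2 * ss.t.sf(t, sum(g.n for g in groups) - 4)
            assert r.p_adjusted >= p_raw - 1e-12

    def test_cdf_monotone_and_critical_value_consistent(self):
        lam = np.sqrt(np.full(4, 8.0) / 16.0)
        grid = np.linspace(0.5, 4.0, 8)
        cdf = dunnett_max_abs_cdf(grid, lam, 28.0)
        assert np.all(np.diff(cdf) > 0)
        c = dunnett_critical_value(lam, 28.0, 0.05)
        assert dunnett_max_abs_cdf(c, lam, 28.0) == pytest.approx(0.95, abs=1e-3)


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self):
        groups = [SampleGroup("a", (1.0, 2.0, 3.0, 4.0)), SampleGroup("b", (2.0, 3.0, 5.0, 9.0))]
        res = tukey_all_pairs(groups)
        ref = ss.ttest_ind([1, 2, 3, 4], [2, 3, 5, 9], equal_var=True)
        assert res[0].p_adjusted == pytest.approx(ref.pvalue, abs=1e-6)

    def test_shifted_groups_all_significant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.01, 6)
        groups = [SampleGroup(f"g{i}", tuple(base + i)) for i in range(3)]
        res = tukey_all_pairs(groups)
        assert len(res) == 3 and all(r.significant for r in res)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        arrays = [rng.normal(0.3 * i, 1, 8) for i in range(4)]
        mine = tukey_all_pairs([SampleGroup(f"g{i}", tuple(a)) for i, a in enumerate(arrays)])
        ref = ss.tukey_hsd(*arrays)
        by_pair = {r.pair: r.p_adjusted for r in mine}
        for i in range(4):
            for j in range(i + 1, 4):
                assert by_pair[(f"g{i}", f"g{j}")] == pytest.approx(ref.pvalue[i, j], abs=1e-9)


class TestShapiroWilk:
    def test_null_rejection_rate(self):
        rng = np.random.default_rng(17)
        rejections = sum(
            shapiro_wilk(rng.normal(0, 1, 5000))[1] < 0.05 for _ in range(500)
        )
        # rate within 0.05 +/- 0.02, asserted on exact counts
        assert 15 <= rejections <= 35

    def test_detects_exponential(self):
        rng = np.random.default_rng(29)
        # strongly skewed sample: the test should reject decisively
        _, p = shapiro_wilk(rng.exponential(1.0, 50))
        assert p < 0.01

    def test_refuses_n2_and_constant(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0] * 10)


class TestFisherExactRxc:
    def test_direction_spectrum_worked_example(self):
        # 2x3 tally of increase/decrease/no-effect calls in the two
        # co-cultivation modes
        p = fisher_exact_rxc(ContingencyTable(((17, 2, 14), (12, 4, 17))))
        assert round(p, 2) == 0.39
        assert p == pytest.approx(0.3865894, abs=1e-6)  # frozen R fisher.test value

    def test_diagonal_2x2(self):
        p = fisher_exact_rxc(ContingencyTable(((5, 0), (0, 5))))
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_modal_table_p_one(self):
        assert fisher_exact_rxc(ContingencyTable(((2, 4, 6), (1, 2, 3)))) == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        _, probs = enumerate_table_probabilities([33, 33], [29, 6, 31])
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_refuses_all_zero_margin(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc(ContingencyTable(((0, 0), (1, 2))))

    def test_enumeration_limit_and_monte_carlo(self):
        big = ContingencyTable(((300, 200), (250, 260)))
        with pytest.raises(ValueError, match="monte-carlo"):
            fisher_exact_rxc(big)
        rng = np.random.default_rng(4)
        p_mc = fisher_exact_rxc(big, method="monte-carlo", n_resamples=20_000, rng=rng)
        ref = ss.fisher_exact(big.array).pvalue
        assert p_mc == pytest.approx(ref, abs=0.02)

    @given(st.lists(st.integers(0, 6), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_2x2_matches_classical_fisher(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        table = ContingencyTable(((a, b), (c, d)))
        p_mine = fisher_exact_rxc(table)
        p_ref = ss.fisher_exact([[a, b], [c, d]]).pvalue
        assert p_mine == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(((1,),))
    with pytest.raises(ValueError):
        ContingencyTable(((1, -2), (3, 4)))
    with pytest.raises(ValueError):
        ContingencyTable(((0, 0), (0, 0)))
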