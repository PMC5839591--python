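import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from randbias.containers import SurvivalTable
from randbias.stats import (
    TwoByTwoTable,
    batch_logrank,
    empirical_percentile,
    fisher_exact,
    hypergeometric_tail,
    logrank_test,
    spearman_distance,
)


def _surv(times, events):
    ids = [f"s{i}" for i in range(len(times))]
    return SurvivalTable(ids, times, events)


class TestLogRank:
    def test_four_sample_worked_example(self):
        # hand accumulation over the four risk sets: O-E = 7/6, V = 17/36
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        res = logrank_test(np.array([True, True, False, False]), surv)
        assert res.statistic == pytest.approx(49 / 17, abs=1e-9)
        assert res.p_value == pytest.approx(sps.chi2.sf(49 / 17, 1), abs=1e-12)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 40
            time = np.round(rng.exponential(50, n), 0)  # induce ties
            event = rng.random(n) < 0.8
            if event.sum() == 0:
                continue
            g = rng.random(n) < 0.5
            if g.all() or (~g).all():
                continue
            surv = _surv(time, event.astype(int))
            mine = logrank_test(g, surv)
            ref = ll_logrank(time[g], time[~g], event[g], event[~g])
            assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_mirror_groups_give_zero_statistic(self):
        # two groups that are sample-for-sample copies of each other
        surv = _surv([5, 5, 9, 9, 12, 12], [1, 1, 0, 0, 1, 1])
        res = logrank_test(np.array([True, False, True, False, True, False]), surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(11)
        surv = _surv(rng.exponential(10, 30), np.ones(30))
        g = rng.random(30) < 0.5
        a = logrank_test(g, surv)
        b = logrank_test(~g, surv)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_all_censored_rejected(self):
        surv = _surv([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            logrank_test(np.array([True, True, False, False]), surv)

    def test_single_group_rejected(self):
        surv = _surv([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            logrank_test(np.array([True, True, True]), surv)

    def test_null_pvalues_uniform(self):
        """Random labels on exchangeable survival give Uniform(0,1) p-values."""
        rng = np.random.default_rng(5)
        n, B = 200, 2000
        time = rng.exponential(100, n)
        event = np.ones(n)
        labels = np.zeros((B, n), dtype=bool)
        for i in range(B):
            labels[i, rng.choice(n, n // 2, replace=False)] = True
        _, p = batch_logrank(labels, time, event)
        ks = sps.kstest(p, "uniform").statistic
        assert ks < 0.05


class TestFisherExact:
    def test_independence_table(self):
        assert fisher_exact(TwoByTwoTable(5, 5, 5, 5)) == (1.0, 1.0)

    def test_enriched_table_against_hand_summation(self):
        odds, p = fisher_exact(TwoByTwoTable(10, 90, 5, 895), side="greater")
        assert odds == pytest.approx(19.888888888, rel=1e-9)
        # direct summation over the margin-fixed support
        expected = sum(
            sps.hypergeom.pmf(k, 1000, 100, 15) for k in range(10, 16)
        )
        assert p == pytest.approx(expected, rel=1e-9)

    def test_single_most_extreme_table(self):
        odds, p = fisher_exact(TwoByTwoTable(3, 0, 0, 3), side="greater")
        assert odds == np.inf
        assert p == pytest.approx(1 / 20, rel=1e-12)  # 1/C(6,3)

    def test_greater_side_equals_hypergeometric_tail_exhaustively(self):
        """One-sided Fisher p == hypergeometric upper tail, all totals <= 30."""
        for total in range(1, 31):
            for a in range(total + 1):
                for b in range(total + 1 - a):
                    for c in range(total + 1 - a - b):
                        d = total - a - b - c
                        _, p = fisher_exact(TwoByTwoTable(a, b, c, d), "greater")
                        tail = hypergeometric_tail(
                            a, a + b, a + c, total
                        )
                        assert p == pytest.approx(tail, rel=1e-9, abs=1e-12)


class TestHypergeometricTail:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0, 3, 3, 10), 1.0),
            ((4, 4, 4, 4), 1.0),
            ((2, 3, 3, 10), 22 / 120),  # [C(3,2)C(7,1)+C(3,3)]/C(10,3)
        ],
    )
    def test_closed_form_values(self, args, expected):
        assert hypergeometric_tail(*args) == pytest.approx(expected, rel=1e-12)

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 3, 3, 10)


class TestSpearmanDistance:
    def test_monotone_transform_is_distance_zero(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        assert spearman_distance(x, np.exp(x)) == pytest.approx(0.0, abs=1e-12)

    def test_reversal_is_distance_two(self):
        x = np.arange(6.0)
        assert spearman_distance(x, x[::-1]) == pytest.approx(2.0, abs=1e-12)

    def test_small_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = (0,1,1,0)
        d = spearman_distance(np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0]))
        assert d == pytest.approx(0.2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman_distance(np.ones(5), np.arange(5.0))


class TestEmpiricalPercentile:
    def test_linear_interpolation_rule(self):
        assert empirical_percentile(np.arange(1, 101), 5) == pytest.approx(5.95)

    def test_extremes_and_singleton(self):
        v = np.array([3.0, 1.0, 2.0])
        assert empirical_percentile(v, 0) == 1.0
        assert empirical_percentile(v, 100) == 3.0
        assert empirical_percentile(np.array([7.0]), 42) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_percentile(np.array([]), 50)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        st.floats(0, 100),
    )
    def test_bounded_by_min_and_max(self, values, q):
        v = np.asarray(values)
        p = empirical_percentile(v, q)
        assert v.min() - 1e-9 <= p <= v.max() + 1e-9
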