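import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from randbias.bias import (
    BiasProfile,
    BiasResult,
    PValueSample,
    median_split,
    null_pvalues,
    pc1_scores,
    proportion_z_test,
    pvalue_diagnostics,
    random_set_pvalues,
    run_bias_analysis,
    sample_gene_set,
    significant_proportion,
)
from randbias.cohort import SyntheticCohortSpec, generate_cohort
from randbias.containers import ExpressionMatrix


class TestSampleGeneSet:
    def test_forced_full_set(self):
        rng = np.random.default_rng(0)
        assert sorted(sample_gene_set(5, 5, rng)) == [0, 1, 2, 3, 4]

    def test_deterministic_and_distinct(self):
        a = sample_gene_set(10, 3, np.random.default_rng(4))
        b = sample_gene_set(10, 3, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)
        assert len(set(a.tolist())) == 3

    def test_uniform_frequency(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(10)
        for _ in range(50_000):
            counts[sample_gene_set(10, 1, rng)[0]] += 1
        assert (np.abs(counts - 5000) < 300).all()  # 3-sigma binomial

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            sample_gene_set(5, 6, np.random.default_rng(0))


class TestPC1Scores:
    def test_rank_one_matrix_recovers_pattern(self):
        v = np.array([1.0, -2.0, 0.5, 0.5])
        lam = np.array([2.0, -1.0, 3.0])
        values = lam[:, None] * v[None, :] + 5.0
        em = ExpressionMatrix(
            values, ["a", "b", "c"], ["s1", "s2", "s3", "s4"], log_transformed=True
        )
        scores = pc1_scores(em)
        vc = v - v.mean()
        corr = abs(np.dot(scores, vc)) / (
            np.linalg.norm(scores) * np.linalg.norm(vc)
        )
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_two_by_three_hand_example(self):
        em = ExpressionMatrix(
            np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]),
            ["a", "b"],
            ["s1", "s2", "s3"],
            log_transformed=True,
        )
        scores = pc1_scores(em)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
        sign = np.sign(scores[2]) or 1.0
        np.testing.assert_allclose(sign * scores, expected, atol=1e-10)

    def test_sign_flip_leaves_split_unchanged(self, null_cohort):
        rng = np.random.default_rng(8)
        idx = sample_gene_set(null_cohort.expression.n_genes, 16, rng)
        scores = pc1_scores(null_cohort.expression.subset_genes(idx))
        np.testing.assert_array_equal(
            median_split(scores), ~median_split(-scores)
        )

    def test_all_constant_rejected(self):
        em = ExpressionMatrix(
            np.ones((3, 5)), list("abc"), [f"s{i}" for i in range(5)], True
        )
        with pytest.raises(ValueError, match="zero variance"):
            pc1_scores(em)


class TestMedianSplit:
    def test_even_clean_split(self):
        np.testing.assert_array_equal(
            median_split(np.array([1.0, 2.0, 3.0, 4.0])),
            [False, False, True, True],
        )

    def test_odd_parity_deterministic(self):
        labels = median_split(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert labels.sum() == 2  # low group takes the tie at the median

    def test_median_ties_balance_groups(self):
        labels = median_split(np.array([1.0, 2.0, 2.0, 3.0]))
        assert labels.sum() == 2
        assert not labels[1] and labels[2]  # ties resolved in input order

    def test_group_sizes_within_one(self):
        rng = np.random.default_rng(2)
        for n in (4, 5, 9, 100, 101):
            labels = median_split(rng.normal(size=n))
            assert abs(int(labels.sum()) - (n - int(labels.sum()))) <= 1

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(np.ones(6))


class TestResampling:
    def test_fixed_seed_reproducible(self, null_cohort):
        a = random_set_pvalues(
            null_cohort.expression, null_cohort.survival, 8, 50, seed=3
        )
        b = random_set_pvalues(
            null_cohort.expression, null_cohort.survival, 8, 50, seed=3
        )
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_zero_draws_rejected(self, null_cohort):
        with pytest.raises(ValueError):
            random_set_pvalues(null_cohort.expression, null_cohort.survival, 8, 0, 1)

    def test_null_cohort_pvalues_uniform(self, null_cohort):
        P = random_set_pvalues(
            null_cohort.expression, null_cohort.survival, 16, 200, seed=5
        )
        assert sps.kstest(P.p_values, "uniform").pvalue > 0.01

    def test_null_assignments_reproducible_and_calibrated(self, null_cohort):
        R1 = null_pvalues(null_cohort.survival, 300, seed=6)
        R2 = null_pvalues(null_cohort.survival, 300, seed=6)
        np.testing.assert_array_equal(R1.p_values, R2.p_values)
        frac = (R1.p_values < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300) + 0.01

    def test_sparse_events_allowed(self):
        from randbias.containers import SurvivalTable

        surv = SurvivalTable(
            [f"s{i}" for i in range(40)],
            np.linspace(1, 40, 40),
            [1] * 5 + [0] * 35,
        )
        R = null_pvalues(surv, 100, seed=1)
        assert len(R.p_values) == 100  # non-uniform is fine, no error


class TestProportionAndZ:
    def test_self_comparison_at_most_nominal(self):
        rng = np.random.default_rng(0)
        v = rng.random(1000)
        S = PValueSample(v, 8, 1000, 0, "random_gene_sets")
        R = PValueSample(v, 0, 1000, 0, "null_assignments")
        thr, prop = significant_proportion(S, R)
        assert prop <= 0.05 + 1e-12

    def test_all_large_pvalues_give_zero(self):
        P = PValueSample(np.ones(5), 8, 5, 0, "random_gene_sets")
        R = PValueSample(np.linspace(0.05, 0.5, 10), 0, 10, 0, "null_assignments")
        assert significant_proportion(P, R)[1] == 0.0

    def test_small_example_counts(self):
        P = PValueSample(
            np.array([0.01, 0.02, 0.60, 0.70, 0.80]), 8, 5, 0, "random_gene_sets"
        )
        R = PValueSample(np.linspace(0.05, 0.5, 10), 0, 10, 0, "null_assignments")
        thr, prop = significant_proportion(P, R)
        assert thr == pytest.approx(0.0725)  # linear-interpolation 5th percentile
        assert prop == 0.4

    def test_z_zero_at_nominal_proportion(self):
        z, p = proportion_z_test(0.05, 5000)
        assert z == 0.0 and p == 1.0

    @pytest.mark.parametrize("prop", [0.80, 0.01])
    def test_z_plug_in_values(self, prop):
        z, p = proportion_z_test(prop, 5000)
        expected = (prop - 0.05) / np.sqrt(
            (prop * (1 - prop) + 0.05 * 0.95) / 5000
        )
        assert z == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(expected)), abs=1e-12)
        assert (z > 0) == (prop > 0.05)


class TestRunBiasAnalysis:
    def test_null_cohort_mostly_unbiased(self, null_cohort):
        prof = run_bias_analysis(
            null_cohort.expression,
            null_cohort.survival,
            set_sizes=(1, 4, 16, 64, 256),
            b=200,
            seed=2,
        )
        n_none = sum(r.direction == "none" for r in prof.results)
        assert n_none >= 4

    def test_signature_cohort_positive_at_64(self, signature_cohort):
        prof = run_bias_analysis(
            signature_cohort.expression,
            signature_cohort.survival,
            set_sizes=(64,),
            b=200,
            seed=2,
        )
        assert prof.results[0].direction == "positive"

    def test_signal_grows_with_set_size_on_average(self):
        """Larger random sets catch more of the latent signature."""
        sizes = (2, 16, 128)
        props = np.zeros((5, len(sizes)))
        for i in range(5):
            c = generate_cohort(
                SyntheticCohortSpec(
                    n_samples=200,
                    n_genes=600,
                    structure="global_signature",
                    signature_fraction=0.3,
                    log_hazard_ratio=1.0,
                    seed=600 + i,
                )
            )
            prof = run_bias_analysis(
                c.expression, c.survival, set_sizes=sizes, b=150, seed=i
            )
            props[i] = [r.prop_signif for r in prof.results]
        mean = props.mean(axis=0)
        assert (np.diff(mean) >= 0).all()

    def test_full_run_deterministic(self, null_cohort):
        kwargs = dict(set_sizes=(4, 32), b=80, seed=17)
        a = run_bias_analysis(null_cohort.expression, null_cohort.survival, **kwargs)
        b = run_bias_analysis(null_cohort.expression, null_cohort.survival, **kwargs)
        assert [dataclasses.asdict(r) for r in a.results] == [
            dataclasses.asdict(r) for r in b.results
        ]

    def test_empty_size_list_rejected(self, null_cohort):
        with pytest.raises(ValueError):
            run_bias_analysis(
                null_cohort.expression, null_cohort.survival, set_sizes=(), b=10
            )

    def test_profile_requires_increasing_sizes(self):
        r = BiasResult(8, 10, 0.05, 0.05, 0.0, 1.0, "none")
        with pytest.raises(ValueError):
            BiasProfile([r, r])


class TestDiagnostics:
    def test_uniform_grid_histogram(self):
        v = (np.arange(100) + 0.5) / 100
        P = PValueSample(v, 8, 100, 0, "random_gene_sets")
        d = pvalue_diagnostics(P, P)
        assert (d["hist_P"] == 5).all()

    def test_self_qq_on_diagonal(self):
        rng = np.random.default_rng(1)
        P = PValueSample(rng.random(500), 8, 500, 0, "random_gene_sets")
        d = pvalue_diagnostics(P, P)
        np.testing.assert_allclose(d["qq_pairs"][:, 0], d["qq_pairs"][:, 1])

    def test_point_mass_cdf_step(self):
        P = PValueSample(np.full(50, 0.3), 8, 50, 0, "random_gene_sets")
        d = pvalue_diagnostics(P, P)
        assert (d["cdf_P"][:, 0] == 0.3).all()
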