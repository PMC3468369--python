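import numpy as np
import pytest
from scipy import stats as sps

from spinesim import (
    ClassificationThresholds,
    ConfigurationError,
    SpineRecord,
    TestSpec,
    classify_spine,
    draw_groups,
    exact_mann_whitney_test,
    ks_two_sample,
    min_attainable_p_u_test,
    per_sample_means,
    run_test,
    students_t_test,
    subclass_fraction,
)
from spinesim.population import Group, Sample
from spinesim.stats_engines import classify_arrays, ks_statistic, mann_whitney_null_counts

from _oracles import mann_whitney_p_bruteforce, min_attainable_p_bruteforce


def _group(*mean_arrays):
    return Group(
        [Sample(f"s{i}", a, a, a, a) for i, a in enumerate(mean_arrays)], "control"
    )


class TestPerSampleMeans:
    def test_simple_means_in_order(self):
        g = _group([1.0, 2.0, 3.0], [5.0, 5.0])
        assert per_sample_means(g, "length").tolist() == [2.0, 5.0]

    def test_one_mean_per_sample(self, source):
        g, _ = draw_groups(source, 7, 20, seed=1)
        assert per_sample_means(g, "area").shape == (7,)


class TestStudentsT:
    def test_worked_example(self):
        # closed form: t = -3.674, df = 4 -> p ~ 0.02131
        p = students_t_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.021312, abs=1e-3)
        t, df = -3.674, 4
        assert p == pytest.approx(2 * sps.t.cdf(t, df), abs=1e-4)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(size=rng.integers(2, 12))
            assert students_t_test(x, y) == pytest.approx(
                sps.ttest_ind(x, y, equal_var=True).pvalue, rel=1e-10
            )

    def test_identical_groups_give_p_one(self):
        assert students_t_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_two_sidedness_symmetry(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=8)
        assert students_t_test(x, y) == students_t_test(y, x)

    def test_separated_constants_sentinel(self):
        assert 0 < students_t_test([1.0, 1.0], [2.0, 2.0]) < 1e-300


class TestExactMannWhitney:
    def test_agrees_with_full_enumeration_for_all_small_sizes(self, rng):
        # exhaustive over all tie-free size pairs with n1 + n2 <= 12
        for n1 in range(1, 12):
            for n2 in range(1, 13 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                assert exact_mann_whitney_test(x, y) == pytest.approx(
                    mann_whitney_p_bruteforce(x, y), abs=1e-12
                ), (n1, n2)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert exact_mann_whitney_test(x, y) == pytest.approx(ref, rel=1e-10)

    @pytest.mark.parametrize("n,expected", [(6, 2 / 924), (7, 2 / 3432)])
    def test_fully_separated_equal_groups(self, n, expected):
        p = exact_mann_whitney_test(np.arange(n), np.arange(n) + 100.0)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_identical_multisets_give_p_one(self):
        assert exact_mann_whitney_test([1.0, 2.0, 2.0], [1.0, 2.0, 2.0]) == 1.0

    def test_null_counts_sum_to_binomial(self):
        from math import comb

        counts = mann_whitney_null_counts(5, 7)
        assert counts.sum() == comb(12, 5)
        assert np.array_equal(counts, counts[::-1])  # symmetric null


class TestMinAttainableP:
    @pytest.mark.parametrize("n", range(1, 9))
    def test_matches_enumeration(self, n):
        assert min_attainable_p_u_test(n, n) == pytest.approx(
            min_attainable_p_bruteforce(n), rel=1e-12
        )

    def test_attainability_boundary_at_alpha_0_001(self):
        # discrete null: groups of <= 6 can never reach p <= 0.001
        assert all(min_attainable_p_u_test(n, n) > 0.001 for n in range(2, 7))
        assert all(min_attainable_p_u_test(n, n) <= 0.001 for n in range(7, 12))

    def test_single_observations(self):
        assert min_attainable_p_u_test(1, 1) == 1.0


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        x = [0.1, 0.5, 0.9]
        assert ks_statistic(x, x) == 0.0
        assert ks_two_sample(x, x) == 1.0

    def test_disjoint_supports_have_full_distance(self):
        assert ks_statistic([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == 1.0

    def test_null_rejection_rate_is_calibrated(self, rng):
        # two samples of 300 from one continuous law: rejection rate ~ alpha
        alpha, reps = 0.05, 4000
        rejections = sum(
            ks_two_sample(rng.random(300), rng.random(300)) < alpha for _ in range(reps)
        )
        rate = rejections / reps
        assert 0.03 < rate < 0.07


class TestClassification:
    def test_rule_examples(self):
        thr = ClassificationThresholds()
        assert classify_spine(SpineRecord(5.0, 0.4, 0.3, 1.0), thr) == "filopodium"
        assert classify_spine(SpineRecord(3.0, 1.0, 1.0, 1.0), thr) == "stubby"
        assert classify_spine(SpineRecord(1.5, 1.5, 1.0, 1.0), thr) == "mushroom"
        assert classify_spine(SpineRecord(1.5, 1.0, 1.0, 1.0), thr) == "thin"

    def test_boundaries(self):
        thr = ClassificationThresholds()
        # strict > for filopodium and stubby; H/N exactly 1.3 -> mushroom
        assert classify_spine(SpineRecord(4.0, 0.2, 0.1, 1.0), thr) != "filopodium"
        assert classify_spine(SpineRecord(2.0, 1.3, 1.0, 1.0), thr) == "mushroom"
        assert classify_spine(SpineRecord(2.0, 1.0, 1.0, 1.0), thr) != "stubby"

    def test_vectorised_matches_scalar(self, source):
        classes = classify_arrays(source.length, source.head_width, source.neck_width)
        sample = source.take(np.arange(200), "c")
        expected = [classify_spine(r) for r in sample.spines()]
        assert classes[:200].tolist() == expected

    def test_total_and_deterministic(self, big_source):
        classes = classify_arrays(
            big_source.length, big_source.head_width, big_source.neck_width
        )
        assert set(np.unique(classes)) <= {"filopodium", "stubby", "mushroom", "thin"}


class TestSubclassFraction:
    def test_simple_fraction(self):
        s = Sample("c", [5.0] * 2 + [1.0] * 8, [0.4] * 10, [0.3] * 10, [0.5] * 10)
        assert subclass_fraction(s, "filopodium") == pytest.approx(0.2)

    def test_population_median_splits_in_half(self, big_source):
        s = big_source.take(np.arange(big_source.n_records), "all")
        med = big_source.median_area()
        assert subclass_fraction(s, ("area_above", med)) == pytest.approx(0.5, abs=0.01)

    def test_empty_predicate_gives_zero(self):
        s = Sample("c", [1.0], [0.4], [0.3], [0.5])
        assert subclass_fraction(s, lambda r: r.length > 100) == 0.0


class TestRunTest:
    @pytest.mark.parametrize("test", ["t_test", "u_test"])
    def test_identical_groups_never_reject(self, source, test):
        g, _ = draw_groups(source, 6, 30, seed=4)
        p, reject = run_test(TestSpec(test=test, alpha=0.01), g, g, "length")
        assert p == 1.0 and not reject

    def test_ks_uses_pooled_spines(self, source, monkeypatch):
        import spinesim.stats_engines as se

        seen = {}

        def spy(a, b):
            seen["sizes"] = (len(a), len(b))
            return 1.0

        monkeypatch.setattr(se, "ks_two_sample", spy)
        g1, g2 = draw_groups(source, 4, 15, seed=5)
        se.run_test(TestSpec(test="ks_test", alpha=0.01), g1, g2, "area")
        assert seen["sizes"] == (60, 60)

    def test_binary_fraction_requires_resolved_threshold(self, source):
        g1, g2 = draw_groups(source, 4, 15, seed=6)
        with pytest.raises(ConfigurationError):
            run_test(TestSpec(test="binary_fraction", alpha=0.01), g1, g2, "area")

    def test_datum_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            TestSpec(test="ks_test", datum="per_sample_mean")

    @pytest.mark.parametrize("test", ["t_test", "u_test", "ks_test"])
    def test_p_symmetric_under_group_swap(self, source, test):
        g1, g2 = draw_groups(source, 6, 20, seed=7)
        spec = TestSpec(test=test, alpha=0.01)
        p_ab, _ = run_test(spec, g1, g2, "head_width")
        p_ba, _ = run_test(spec, g2, g1, "head_width")
        assert p_ab == pytest.approx(p_ba, rel=1e-12)
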