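import numpy as np
import pytest

from spinesim import (
    ChangeModel,
    ConfigurationError,
    ExperimentConfig,
    TestSpec,
    estimate_false_negative_rate,
    estimate_false_positive_rate,
    find_min_samples,
    fpr_sigma_sweep,
    power_table,
    run_single_experiment,
    simulate_pvalues,
)
from spinesim.population import PopulationSource
from spinesim.simulator import ErrorRateEstimate


@pytest.fixture
def growth_config(source):
    return ExperimentConfig(
        n=8,
        m=60,
        variable="head_width",
        change=ChangeModel(kind="linear_growth", variable="head_width", factor=1.2),
        test=TestSpec(test="t_test", alpha=0.01),
        population=source,
        seed=5,
    )


class TestConfigValidation:
    def test_bad_sizes(self):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(n=1)
        with pytest.raises(ConfigurationError):
            ExperimentConfig(m=0)
        with pytest.raises(ConfigurationError):
            ExperimentConfig(variable="volume")

    def test_fnr_requires_real_change(self, source):
        cfg = ExperimentConfig(population=source)
        with pytest.raises(ConfigurationError):
            estimate_false_negative_rate(cfg, runs=10)

    def test_fpr_rejects_treatment_changes(self, growth_config):
        with pytest.raises(ConfigurationError):
            estimate_false_positive_rate(growth_config, runs=10)


class TestSingleRun:
    def test_degenerate_source_never_rejects(self):
        # a one-record source forces identical groups, hence p = 1
        src = PopulationSource([1.0], [0.4], [0.3], [0.5], ["c1"])
        cfg = ExperimentConfig(n=3, m=5, population=src)
        assert run_single_experiment(cfg, seed=0) is False

    def test_extreme_effect_always_detected(self, source):
        cfg = ExperimentConfig(
            n=8, m=60, variable="length",
            change=ChangeModel(kind="linear_growth", variable="length", factor=10.0),
            population=source,
        )
        assert all(run_single_experiment(cfg, seed=s, source=source) for s in range(20))


class TestReproducibility:
    def test_identical_master_seed_identical_pvalues(self, growth_config):
        a = simulate_pvalues(growth_config, runs=50, master_seed=9)
        b = simulate_pvalues(growth_config, runs=50, master_seed=9)
        assert np.array_equal(a, b)

    def test_different_seeds_agree_within_binomial_noise(self, growth_config):
        cfg = growth_config.with_(n=4)
        r1 = estimate_false_negative_rate(cfg, runs=400, master_seed=1)
        r2 = estimate_false_negative_rate(cfg, runs=400, master_seed=2)
        pooled_se = np.sqrt(r1.se() ** 2 + r2.se() ** 2)
        assert abs(r1.rate - r2.rate) < 4 * pooled_se


class TestErrorRates:
    def test_no_effect_change_misses_at_one_minus_alpha(self, source):
        cfg = ExperimentConfig(
            n=6, m=30,
            change=ChangeModel(kind="linear_growth", variable="head_width", factor=1.0),
            test=TestSpec(alpha=0.01),
            population=source,
        )
        est = estimate_false_negative_rate(cfg, runs=500)
        assert est.ci95[0] <= 0.99 <= est.ci95[1] or est.rate > 0.97

    def test_fnr_nonincreasing_in_n(self, source):
        rates = []
        for i, n in enumerate((4, 8, 16, 32)):
            cfg = ExperimentConfig(
                n=n, m=60, variable="head_width",
                change=ChangeModel(kind="linear_growth", variable="head_width", factor=1.1),
                test=TestSpec(alpha=0.01),
                population=source,
            )
            rates.append(estimate_false_negative_rate(cfg, runs=300, cell_index=i))
        for lo, hi in zip(rates, rates[1:]):
            slack = 2 * np.sqrt(lo.se() ** 2 + hi.se() ** 2)
            assert hi.rate <= lo.rate + slack

    def test_null_fpr_near_alpha(self, source):
        cfg = ExperimentConfig(n=8, m=60, population=source, test=TestSpec(alpha=0.01))
        est = estimate_false_positive_rate(cfg, runs=2000)
        assert est.ci95[0] <= 0.01 <= est.ci95[1]

    def test_estimate_invariants(self):
        est = ErrorRateEstimate.from_events(3, 100)
        assert est.rate == 0.03 and est.n_runs == 100
        assert est.ci95[0] <= est.rate <= est.ci95[1]


class TestFindMinSamples:
    def test_extreme_effect_needs_two_or_three_samples(self, source):
        cfg = ExperimentConfig(
            m=60, variable="head_width",
            change=ChangeModel(kind="linear_growth", variable="head_width", factor=3.0),
            test=TestSpec(alpha=0.01),
            population=source,
        )
        res = find_min_samples(cfg, runs=200)
        assert res.found and res.n in (2, 3)

    def test_auto_and_scan_searches_agree(self, source):
        cfg = ExperimentConfig(
            m=60, variable="head_width",
            change=ChangeModel(kind="linear_growth", variable="head_width", factor=1.5),
            test=TestSpec(alpha=0.01),
            population=source,
        )
        auto = find_min_samples(cfg, runs=300, search="auto")
        scan = find_min_samples(cfg, runs=300, search="scan")
        assert auto.found and scan.found
        assert abs(auto.n - scan.n) <= 1  # same per-n streams; MC boundary wiggle

    def test_unreachable_returns_sentinel_with_rate(self, source):
        cfg = ExperimentConfig(
            m=5, variable="area",
            change=ChangeModel(kind="linear_growth", variable="area", factor=1.01),
            test=TestSpec(alpha=0.001),
            population=source,
        )
        res = find_min_samples(cfg, runs=100, n_max=6)
        assert not res.found and res.n is None
        assert res.fnr.rate > 0.5  # hopeless effect: FNR at n_max still large

    def test_wilson_upper_criterion_is_no_looser(self, source):
        cfg = ExperimentConfig(
            m=60, variable="head_width",
            change=ChangeModel(kind="linear_growth", variable="head_width", factor=1.5),
            test=TestSpec(alpha=0.01),
            population=source,
        )
        point = find_min_samples(cfg, runs=300, criterion="point")
        strict = find_min_samples(cfg, runs=300, criterion="wilson_upper")
        assert strict.n >= point.n


class TestTables:
    def test_single_cell_grid(self, source):
        table = power_table(
            magnitudes=(0.5,), alphas=(0.01,), variables=("head_width",),
            m_values=(60,), runs=100, seed=3, population=source,
        )
        assert len(table.rows) == 1
        row = table.rows.iloc[0]
        assert row["minimal_n"] >= 2 and row["found"]

    def test_grid_shape_and_audit(self, source):
        table = power_table(
            magnitudes=(0.2, 0.5), alphas=(0.01,), variables=("head_width",),
            m_values=(30, 60), runs=150, seed=3, population=source,
        )
        assert len(table.rows) == 4
        assert set(table.pivot().columns) == {30, 60}
        assert table.monotonicity_violations(slack=1) == []

    def test_sigma_sweep_null_point(self, source):
        df = fpr_sigma_sweep(
            [0.0], m_values=(15,), alpha=0.01, runs=600, seed=2, population=source
        )
        assert len(df) == 1
        assert df["ci_low"][0] <= 0.01 <= df["ci_high"][0] + 0.005
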