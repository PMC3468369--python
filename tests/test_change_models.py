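import numpy as np
import pytest

from spinesim import (
    ChangeModel,
    ConfigurationError,
    Sample,
    apply_filopodia_elimination,
    apply_head_swelling,
    apply_linear_growth,
    apply_small_spine_growth,
    apply_systematic_perturbation,
)
from spinesim.change_models import apply_change
from spinesim.population import VARIABLES

from _oracles import eliminate_and_refill_once


@pytest.fixture
def sample(source):
    return source.take(np.arange(60), "cell-1")


class TestLinearGrowth:
    def test_identity_at_factor_one(self, sample):
        assert apply_linear_growth(sample, "length", 1.0) == sample

    def test_half_micron_head_grows_to_three_quarters(self):
        s = Sample("c", [1.0], [0.50], [0.30], [0.60])
        out = apply_linear_growth(s, "head_width", 1.5)
        assert out.head_width[0] == pytest.approx(0.75)
        assert out.length[0] == 1.0 and out.area[0] == 0.60  # untouched

    def test_multiplicativity(self, sample):
        twice = apply_linear_growth(apply_linear_growth(sample, "area", 1.1), "area", 1.1)
        once = apply_linear_growth(sample, "area", 1.21)
        assert np.allclose(twice.area, once.area)

    def test_unknown_variable_rejected(self, sample):
        with pytest.raises(ConfigurationError):
            apply_linear_growth(sample, "volume", 1.2)

    def test_head_swelling_is_head_width_growth(self, sample):
        assert apply_head_swelling(sample, 1.3) == apply_linear_growth(
            sample, "head_width", 1.3
        )


class TestFilopodiaElimination:
    def test_probability_zero_is_identity(self, sample, source):
        out = apply_filopodia_elimination(sample, source, p_elim=0.0, seed=1)
        assert out == sample

    def test_probability_one_removes_all_long_spines(self, sample, source):
        out = apply_filopodia_elimination(sample, source, length_threshold=2.0, p_elim=1.0, seed=1)
        assert out.m == sample.m
        assert np.all(out.length <= 2.0)

    def test_seeded_reproducibility(self, sample, source):
        a = apply_filopodia_elimination(sample, source, seed=5)
        b = apply_filopodia_elimination(sample, source, seed=5)
        assert a == b

    def test_below_threshold_replacement_pool(self, sample, source):
        out = apply_filopodia_elimination(
            sample, source, p_elim=1.0, seed=2, replacement_pool="below_threshold"
        )
        assert np.all(out.length <= 2.0)

    def test_surviving_long_fraction_matches_closed_form_and_oracle(self, source):
        # each output slot holds a source draw conditioned on surviving the
        # elimination filter: P(L > thr) becomes q(1-p) / (1 - p q)
        thr, p = 2.0, 0.5
        q = (source.length > thr).mean()
        expected = q * (1 - p) / (1 - p * q)

        rng = np.random.default_rng(99)
        longs = []
        for i in range(400):
            s = source.take(rng.integers(0, source.n_records, 250), "c")
            out = apply_filopodia_elimination(s, source, thr, p, seed=int(rng.integers(2**31)))
            longs.append((out.length > thr).mean())
        ours = np.mean(longs)

        oracle_rng = np.random.default_rng(17)
        oracle = np.mean(
            [
                (
                    eliminate_and_refill_once(
                        source.length[oracle_rng.integers(0, source.n_records, 250)],
                        source.length, thr, p, oracle_rng,
                    )
                    > thr
                ).mean()
                for _ in range(400)
            ]
        )
        assert ours == pytest.approx(expected, abs=0.01)
        assert ours == pytest.approx(oracle, abs=0.01)


class TestSmallSpineGrowth:
    def test_small_spine_grows(self):
        s = Sample("c", [1.0], [0.4], [0.3], [0.5])
        assert apply_small_spine_growth(s).area[0] == pytest.approx(0.75)

    def test_above_threshold_untouched(self):
        s = Sample("c", [1.0], [0.4], [0.3], [0.9])
        assert apply_small_spine_growth(s).area[0] == 0.9

    def test_membership_decided_on_prechange_area(self):
        # 0.79 crosses the 0.8 threshold after growth but is modified once
        s = Sample("c", [1.0], [0.4], [0.3], [0.79])
        assert apply_small_spine_growth(s).area[0] == pytest.approx(1.185)


class TestSystematicPerturbation:
    def test_sigma_zero_is_identity(self, sample):
        assert apply_systematic_perturbation(sample, "area", 0.0, seed=1) == sample

    def test_single_shared_factor_within_sample(self, sample):
        out = apply_systematic_perturbation(sample, "length", 0.1, seed=3)
        ratios = out.length / sample.length
        assert np.allclose(ratios, ratios[0])
        assert np.all(out.head_width == sample.head_width)

    def test_factor_spread_matches_sigma(self, sample):
        factors = [
            apply_systematic_perturbation(sample, "area", 0.1, seed=s).area[0]
            / sample.area[0]
            for s in range(10_000)
        ]
        assert np.std(factors) == pytest.approx(0.1, rel=0.05)
        assert np.mean(factors) == pytest.approx(1.0, abs=0.005)


@pytest.mark.parametrize(
    "change",
    [
        ChangeModel(kind="linear_growth", variable="length", factor=1.5),
        ChangeModel(kind="head_swelling", factor=1.2),
        ChangeModel(kind="filopodia_elimination"),
        ChangeModel(kind="small_spine_growth", factor=1.5),
        ChangeModel(kind="systematic_perturbation", variable="area", sigma=0.15),
    ],
    ids=lambda c: c.kind,
)
def test_every_change_preserves_count_and_invariants(change, sample, source, rng):
    out = apply_change(change, sample, source, rng)
    assert out.m == sample.m
    for v in VARIABLES:
        arr = out.values(v)
        assert np.all(np.isfinite(arr)) and np.all(arr > 0)


def test_change_model_validation():
    with pytest.raises(ConfigurationError):
        ChangeModel(kind="shrinkage")
    with pytest.raises(ConfigurationError):
        ChangeModel(kind="linear_growth", factor=0.0)
    with pytest.raises(ConfigurationError):
        ChangeModel(kind="filopodia_elimination", elimination_probability=1.5)
    with pytest.raises(ConfigurationError):
        ChangeModel.from_dict({"kind": "linear_growth", "magnitude": 0.2})
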