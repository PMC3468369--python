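"""Statistical comparisons between spine groups.

Three comparison strategies are implemented, matching how morphometric
experiments are actually analysed:

* **per-sample means** — the statistical unit is one variable averaged over
  all spines of a cell/animal; groups of such means are compared with the
  equal-variance two-tailed Student t-test or the exact two-tailed
  Mann–Whitney(-Wilcoxon) u-test;
* **pooled distributions** — all n·m spine values of a group are pooled and
  compared with the two-sample Kolmogorov–Smirnov test (sensitive to
  subpopulation changes, but blind to which sample a spine came from);
* **subclass fractions** — spines are classified (filopodium / stubby /
  mushroom / thin, or binary large/small by area) and the per-sample class
  fractions are compared with the t-test.

The u-test uses the exact permutation null distribution of the rank-sum
statistic wherever feasible; because that distribution is discrete, small
groups cannot reach small significance levels at all
(:func:`min_attainable_p_u_test`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import comb

import numpy as np
from scipy import special
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError
from .population import Group, Sample, SpineRecord, _check_variable

__all__ = [
    "TestSpec",
    "ClassificationThresholds",
    "SPINE_CLASSES",
    "per_sample_means",
    "students_t_test",
    "exact_mann_whitney_test",
    "mann_whitney_null_counts",
    "min_attainable_p_u_test",
    "ks_two_sample",
    "ks_statistic",
    "classify_spine",
    "classify_arrays",
    "subclass_fraction",
    "run_test",
]

logger = logging.getLogger(__name__)

SPINE_CLASSES = ("filopodium", "stubby", "mushroom", "thin")

TESTS = ("t_test", "u_test", "ks_test", "subclass_fraction", "binary_fraction")

#: Default datum (statistical unit) for each test.
_TEST_DATUM = {
    "t_test": "per_sample_mean",
    "u_test": "per_sample_mean",
    "ks_test": "pooled_spines",
    "subclass_fraction": "per_sample_fraction",
    "binary_fraction": "per_sample_fraction",
}

# Exact/approximate switchover constants, fixed for cross-machine
# reproducibility (documented here rather than left to library defaults).
U_EXACT_MIN_SIDE = 15     # exact u-test when min(n1, n2) <= this ...
U_EXACT_MAX_TOTAL = 40    # ... and n1 + n2 <= this, ties absent
KS_ASYMPTOTIC_EN = 35.0   # asymptotic K-S when n1*n2/(n1+n2) >= this


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the shape classification and the binary area split.

    A spine is a *filopodium* if L > ``filopodium_min_length`` (strict), else
    *stubby* if L/N > ``stubby_min_ln_ratio`` (strict), else *mushroom* if
    H/N ≥ ``mushroom_min_hn_ratio`` and *thin* otherwise.  The boundary
    H/N = 1.3 is assigned to mushroom so the rule is total.

    ``binary_area_threshold`` splits spines into large/small by area; when
    ``None`` it is resolved at experiment setup to the median area of the
    base population (≈0.65 μm² for the original measured culture).
    """

    filopodium_min_length: float = 4.0
    stubby_min_ln_ratio: float = 2.0
    mushroom_min_hn_ratio: float = 1.3
    binary_area_threshold: float | None = None

    def __post_init__(self):
        for name in ("filopodium_min_length", "stubby_min_ln_ratio", "mushroom_min_hn_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.binary_area_threshold is not None and self.binary_area_threshold <= 0:
            raise ConfigurationError("binary_area_threshold must be positive")

    def to_dict(self) -> dict:
        return {
            "filopodium_min_length": self.filopodium_min_length,
            "stubby_min_ln_ratio": self.stubby_min_ln_ratio,
            "mushroom_min_hn_ratio": self.mushroom_min_hn_ratio,
            "binary_area_threshold": self.binary_area_threshold,
        }


@dataclass(frozen=True)
class TestSpec:
    """Which test to run, at what significance level, on which datum."""

    __test__ = False  # not a pytest test class, despite the name

    test: str = "t_test"
    alpha: float = 0.01
    datum: str | None = None
    subclass: str = "mushroom"
    thresholds: ClassificationThresholds = ClassificationThresholds()

    def __post_init__(self):
        if self.test not in TESTS:
            raise ConfigurationError(f"unknown test {self.test!r}; expected one of {TESTS}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"test.alpha must be in (0, 1), got {self.alpha}")
        if self.datum is None:
            object.__setattr__(self, "datum", _TEST_DATUM[self.test])
        elif self.datum != _TEST_DATUM[self.test]:
            raise ConfigurationError(
                f"test {self.test!r} requires datum {_TEST_DATUM[self.test]!r}, "
                f"got {self.datum!r}"
            )
        if self.test == "subclass_fraction" and self.subclass not in SPINE_CLASSES:
            raise ConfigurationError(
                f"subclass must be one of {SPINE_CLASSES}, got {self.subclass!r}"
            )

    def with_binary_threshold(self, threshold: float) -> "TestSpec":
        return replace(self, thresholds=replace(self.thresholds, binary_area_threshold=threshold))

    def to_dict(self) -> dict:
        d = {"name": self.test, "alpha": self.alpha}
        if self.test == "subclass_fraction":
            d["subclass"] = self.subclass
        thr = self.thresholds
        if thr != ClassificationThresholds():
            d["thresholds"] = thr.to_dict()
        return d


# ---------------------------------------------------------------------------
# Per-sample statistics


def per_sample_means(group: Group, variable: str) -> np.ndarray:
    """One arithmetic mean of ``variable`` per sample, order-preserving."""
    _check_variable(variable)
    out = np.empty(group.n)
    for i, s in enumerate(group.samples):
        if s.m < 1:  # Sample construction forbids this, but guard anyway
            raise ValidationError(f"sample {s.sample_id!r} is empty")
        out[i] = s.values(variable).mean()
    return out


# ---------------------------------------------------------------------------
# Student t-test


def students_t_test(x, y) -> float:
    """Classic equal-variance two-sample two-tailed Student t-test p-value.

    Degenerate inputs follow fixed conventions: zero pooled variance with
    equal means gives p = 1 (no evidence of difference); zero pooled variance
    with unequal means gives a logged p = 5e-324 sentinel (perfect
    separation of constants).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"t-test needs at least 2 values per group, got {n1} and {n2}")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    dm = x.mean() - y.mean()
    if sp2 == 0:
        if dm == 0:
            return 1.0
        logger.warning("t-test: zero pooled variance with unequal means; returning 0+ sentinel")
        return 5e-324
    t = dm / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    # stdtr is the Student-t CDF; two-tailed p
    return float(2.0 * special.stdtr(df, -abs(t)))


# ---------------------------------------------------------------------------
# Exact Mann-Whitney u-test


def mann_whitney_null_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of the Mann–Whitney U statistic.

    Entry u holds the number of the C(n1+n2, n1) equally likely rank
    assignments with U = u, for u = 0 .. n1·n2, computed by the Gaussian
    binomial (partition-count) recurrence.  Counts are exact in float64 for
    the supported sizes (C(40, 20) < 2^53).
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    umax = n1 * n2
    ways = np.zeros(umax + 1)
    ways[0] = 1.0
    for i in range(1, n1 + 1):
        # multiply by 1 / (1 - x^i): prefix sums with stride i
        for u in range(i, umax + 1):
            ways[u] += ways[u - i]
        # multiply by (1 - x^(n2 + i))
        shift = n2 + i
        if shift <= umax:
            ways[shift:] -= ways[: umax + 1 - shift].copy()
    return ways


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    allv = np.concatenate([x, y])
    ranks = sps.rankdata(allv)  # midranks under ties
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def exact_mann_whitney_test(x, y) -> float:
    """Two-tailed Mann–Whitney u-test p-value.

    The exact permutation distribution of U is enumerated whenever the input
    is tie-free, min(n1, n2) ≤ 15 and n1+n2 ≤ 40; two-tailed p is
    2·min(P(U ≤ u), P(U ≥ u)) capped at 1.  Larger or tied inputs fall back
    to the continuity-corrected normal approximation with midranks and tie
    correction; exactness is asserted only for tie-free inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("u-test needs at least 1 value per group")
    u = _u_statistic(x, y)

    allv = np.concatenate([x, y])
    has_ties = np.unique(allv).size < allv.size
    if not has_ties and min(n1, n2) <= U_EXACT_MIN_SIDE and n1 + n2 <= U_EXACT_MAX_TOTAL:
        counts = mann_whitney_null_counts(n1, n2)
        total = counts.sum()
        k = int(round(u))
        cdf = counts[: k + 1].sum() / total
        sf = counts[k:].sum() / total
        return float(min(1.0, 2.0 * min(cdf, sf)))

    # normal approximation with tie correction and continuity correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * special.ndtr(-z)))


def min_attainable_p_u_test(n1: int, n2: int) -> float:
    """Smallest two-tailed p the exact u-test can produce: 2 / C(n1+n2, n1).

    Because the exact null distribution is discrete, the most extreme rank
    arrangement has probability 1/C(n1+n2, n1) per tail; with equal groups of
    6 this floor is 2/924 ≈ 0.00216 > 0.001, so at significance 0.001 the
    u-test can never reject for n ≤ 6 — the smallest workable group is 7.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    return min(1.0, 2.0 / comb(n1 + n2, n1))


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def ks_statistic(a, b) -> float:
    """Supremum distance between the two empirical CDFs."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / a.size
    cdf_b = np.searchsorted(b, allv, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_two_sample(a, b) -> float:
    """Two-sided two-sample Kolmogorov–Smirnov p-value.

    Uses the exact small-sample distribution while the effective size
    n1·n2/(n1+n2) is below ``KS_ASYMPTOTIC_EN`` and the asymptotic
    Kolmogorov distribution above; the switchover is a fixed constant so
    results are reproducible across machines.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("K-S test needs at least 2 values per group")
    en = a.size * b.size / (a.size + b.size)
    method = "exact" if en < KS_ASYMPTOTIC_EN else "asymp"
    return float(sps.ks_2samp(a, b, method=method).pvalue)


# ---------------------------------------------------------------------------
# Classification


def classify_spine(record: SpineRecord, thresholds: ClassificationThresholds | None = None) -> str:
    """Assign one spine to filopodium / stubby / mushroom / thin.

    Rules are applied in order: filopodium first (L strictly above the length
    threshold), then stubby (L/N strictly above its ratio threshold), then
    the mushroom/thin dichotomy on H/N (boundary value → mushroom).
    """
    thr = thresholds or ClassificationThresholds()
    if record.length > thr.filopodium_min_length:
        return "filopodium"
    if record.length / record.neck_width > thr.stubby_min_ln_ratio:
        return "stubby"
    if record.head_width / record.neck_width >= thr.mushroom_min_hn_ratio:
        return "mushroom"
    return "thin"


def classify_arrays(
    length: np.ndarray,
    head_width: np.ndarray,
    neck_width: np.ndarray,
    thresholds: ClassificationThresholds | None = None,
) -> np.ndarray:
    """Vectorised :func:`classify_spine`; returns an array of class names."""
    thr = thresholds or ClassificationThresholds()
    out = np.where(
        length > thr.filopodium_min_length,
        "filopodium",
        np.where(
            length / neck_width > thr.stubby_min_ln_ratio,
            "stubby",
            np.where(head_width / neck_width >= thr.mushroom_min_hn_ratio, "mushroom", "thin"),
        ),
    )
    return out


def subclass_fraction(sample: Sample, predicate, thresholds=None) -> float:
    """Fraction of a sample's spines satisfying ``predicate``.

    ``predicate`` may be a shape-class name, a tuple ``("area_above", thr)``
    or ``("area_below", thr)``, or a callable on :class:`SpineRecord`.
    """
    if sample.m < 1:
        raise ValidationError("cannot take a subclass fraction of an empty sample")
    if isinstance(predicate, str):
        if predicate not in SPINE_CLASSES:
            raise ConfigurationError(
                f"unknown spine class {predicate!r}; expected one of {SPINE_CLASSES}"
            )
        classes = classify_arrays(
            sample.length, sample.head_width, sample.neck_width, thresholds
        )
        return float((classes == predicate).mean())
    if isinstance(predicate, tuple) and len(predicate) == 2:
        mode, thr = predicate
        if mode == "area_above":
            return float((sample.area > thr).mean())
        if mode == "area_below":
            return float((sample.area <= thr).mean())
        raise ConfigurationError(f"unknown area predicate {mode!r}")
    if callable(predicate):
        return float(np.mean([bool(predicate(r)) for r in sample.spines()]))
    raise ConfigurationError(f"unsupported predicate {predicate!r}")


# ---------------------------------------------------------------------------
# Dispatch


def _fractions(group: Group, spec: TestSpec) -> np.ndarray:
    if spec.test == "binary_fraction":
        thr = spec.thresholds.binary_area_threshold
        if thr is None:
            raise ConfigurationError(
                "binary_fraction requires thresholds.binary_area_threshold "
                "(resolve it from the base population median area first)"
            )
        pred = ("area_above", thr)
    else:
        pred = spec.subclass
    return np.array([subclass_fraction(s, pred, spec.thresholds) for s in group.samples])


def run_test(spec: TestSpec, control: Group, treatment: Group, variable: str) -> tuple:
    """Run one comparison; returns ``(p, reject)`` with reject ⇔ p < alpha.

    The datum follows the test: per-sample means for the t- and u-tests,
    pooled spine values for K-S, per-sample class fractions for the
    subclass tests.
    """
    control.require_comparable()
    treatment.require_comparable()
    if spec.test in ("t_test", "u_test"):
        x = per_sample_means(control, variable)
        y = per_sample_means(treatment, variable)
        p = students_t_test(x, y) if spec.test == "t_test" else exact_mann_whitney_test(x, y)
    elif spec.test == "ks_test":
        p = ks_two_sample(control.pooled(variable), treatment.pooled(variable))
    else:
        p = students_t_test(_fractions(control, spec), _fractions(treatment, spec))
    return p, bool(p < spec.alpha)
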