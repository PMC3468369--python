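"""Treatment-effect models applied to samples of spines.

Four families of simulated morphological change are supported, plus the
per-sample systematic perturbation used in false-positive analysis:

* ``linear_growth`` — every spine's chosen variable multiplied by a factor
  (10/20/50% growth are factors 1.1/1.2/1.5); ``head_swelling`` is its
  restriction to the head width, other variables untouched.
* ``filopodia_elimination`` — each spine longer than a threshold (default
  2 μm) is removed with a given probability (default 0.5) and replaced by a
  fresh draw from the base population subject to the same elimination rule,
  so the spine count m is preserved while the length spectrum shifts toward
  mature spines.
* ``small_spine_growth`` — spines whose pre-change area falls below a
  threshold (default 0.8 μm²) have that area multiplied by a factor
  (default 1.5); membership is decided on the pre-change value.
* ``systematic_perturbation`` — one Gaussian factor (mean 1, SD σ, redrawn
  until positive) per sample multiplies the chosen variable of every spine
  in that sample, modelling cell/animal/preparation effects that are not
  spine-sampling noise.  Note σ is the *standard deviation* of the factor,
  swept in the 5–15% range.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rand import as_rng
from .errors import ConfigurationError, SamplingError
from .population import PopulationSource, Sample, _check_variable

__all__ = [
    "CHANGE_KINDS",
    "ChangeModel",
    "apply_linear_growth",
    "apply_head_swelling",
    "apply_filopodia_elimination",
    "apply_small_spine_growth",
    "apply_systematic_perturbation",
    "apply_change",
]

CHANGE_KINDS = (
    "none",
    "linear_growth",
    "head_swelling",
    "filopodia_elimination",
    "small_spine_growth",
    "systematic_perturbation",
)


@dataclass(frozen=True)
class ChangeModel:
    """Tagged description of a treatment effect.

    Only the fields relevant to ``kind`` are used; the rest keep their
    defaults.  ``requires_rng`` distinguishes the stochastic models
    (elimination, perturbation) from the deterministic ones.
    """

    kind: str = "none"
    variable: str = "length"
    factor: float = 1.0
    length_threshold: float = 2.0
    elimination_probability: float = 0.5
    area_threshold: float = 0.8
    sigma: float = 0.0
    replacement_pool: str = "full"  # or "below_threshold"

    def __post_init__(self):
        if self.kind not in CHANGE_KINDS:
            raise ConfigurationError(
                f"unknown change kind {self.kind!r}; expected one of {CHANGE_KINDS}"
            )
        if self.kind in ("linear_growth", "head_swelling", "systematic_perturbation"):
            _check_variable(self.variable)
        if self.factor <= 0:
            raise ConfigurationError(f"factor must be > 0, got {self.factor}")
        if not (0.0 <= self.elimination_probability <= 1.0):
            raise ConfigurationError(
                f"elimination_probability must be in [0, 1], got {self.elimination_probability}"
            )
        if self.length_threshold <= 0 or self.area_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")
        if self.replacement_pool not in ("full", "below_threshold"):
            raise ConfigurationError(
                f"replacement_pool must be 'full' or 'below_threshold', got {self.replacement_pool!r}"
            )

    @property
    def requires_rng(self) -> bool:
        return self.kind in ("filopodia_elimination", "systematic_perturbation")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind in ("linear_growth", "systematic_perturbation"):
            d["variable"] = self.variable
        if self.kind in ("linear_growth", "head_swelling", "small_spine_growth"):
            d["factor"] = self.factor
        if self.kind == "filopodia_elimination":
            d["length_threshold"] = self.length_threshold
            d["elimination_probability"] = self.elimination_probability
            d["replacement_pool"] = self.replacement_pool
        if self.kind == "small_spine_growth":
            d["area_threshold"] = self.area_threshold
        if self.kind == "systematic_perturbation":
            d["sigma"] = self.sigma
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChangeModel":
        unknown = set(d) - {
            "kind", "variable", "factor", "length_threshold",
            "elimination_probability", "area_threshold", "sigma",
            "replacement_pool",
        }
        if unknown:
            raise ConfigurationError(f"change: unknown key(s) {sorted(unknown)}")
        return cls(**d)


def apply_linear_growth(sample: Sample, variable: str, factor: float) -> Sample:
    """Multiply one morphometric variable of every spine by ``factor``.

    Deterministic; other variables and the spine count are untouched.
    """
    _check_variable(variable)
    if factor <= 0:
        raise ConfigurationError(f"growth factor must be > 0, got {factor}")
    return sample.replace(**{variable: sample.values(variable) * factor})


def apply_head_swelling(sample: Sample, factor: float) -> Sample:
    """Spine-head swelling: linear growth of the head width only."""
    return apply_linear_growth(sample, "head_width", factor)


def apply_filopodia_elimination(
    sample: Sample,
    source: PopulationSource,
    length_threshold: float = 2.0,
    p_elim: float = 0.5,
    seed=None,
    replacement_pool: str = "full",
) -> Sample:
    """Eliminate long spines with probability ``p_elim`` and refill to m spines.

    Each spine with L > ``length_threshold`` is removed independently with
    probability ``p_elim``.  Removed spines are replaced by fresh draws from
    ``source``; with ``replacement_pool="full"`` (default) every replacement
    passes through the same elimination rule (redrawn until it survives),
    with ``"below_threshold"`` replacements are drawn directly from the
    sub-threshold part of the source.  Either way the output has exactly m
    spines and its length spectrum is shifted toward mature spines.
    """
    if not source.usable:
        raise SamplingError("filopodia elimination needs a non-empty source")
    rng = as_rng(seed)
    keep = ~((sample.length > length_threshold) & (rng.random(sample.m) < p_elim))

    if replacement_pool == "below_threshold":
        pool = np.flatnonzero(source.length <= length_threshold)
        if pool.size == 0 and not np.all(keep):
            raise SamplingError(
                f"no source spine has length <= {length_threshold}; cannot refill"
            )
    elif replacement_pool != "full":
        raise ConfigurationError(
            f"replacement_pool must be 'full' or 'below_threshold', got {replacement_pool!r}"
        )

    cols = {v: [sample.values(v)[keep]] for v in ("length", "head_width", "neck_width", "area")}
    deficit = int(sample.m - keep.sum())
    while deficit > 0:
        # draw in batches; survivors of the same elimination rule fill the gap
        batch = max(2 * deficit, 16)
        if replacement_pool == "full":
            idx = rng.integers(0, source.n_records, size=batch)
            L = source.length[idx]
            surv = ~((L > length_threshold) & (rng.random(batch) < p_elim))
            idx = idx[surv][:deficit]
        else:
            idx = pool[rng.integers(0, pool.size, size=min(batch, deficit))][:deficit]
        for v in cols:
            cols[v].append(source.values(v)[idx])
        deficit -= idx.size

    out = {v: np.concatenate(parts) for v, parts in cols.items()}
    return Sample(sample.sample_id, **out)


def apply_small_spine_growth(
    sample: Sample, area_threshold: float = 0.8, factor: float = 1.5
) -> Sample:
    """Grow the area of every spine whose *pre-change* area is below threshold.

    Membership in the "small" subpopulation is decided once, on the original
    area, so a spine crossing the threshold is still modified exactly once.
    """
    if factor <= 0:
        raise ConfigurationError(f"growth factor must be > 0, got {factor}")
    if area_threshold <= 0:
        raise ConfigurationError(f"area threshold must be > 0, got {area_threshold}")
    small = sample.area < area_threshold
    area = np.where(small, sample.area * factor, sample.area)
    return sample.replace(area=area)


def apply_systematic_perturbation(
    sample: Sample, variable: str, sigma: float, seed=None
) -> Sample:
    """Multiply one variable of every spine by a single per-sample factor.

    The factor is drawn once per sample from Normal(1, σ²) and redrawn until
    positive; for the σ ≤ 0.2 range studied the truncation is negligible and
    the factor mean stays ≈ 1.
    """
    _check_variable(variable)
    if sigma < 0:
        raise ConfigurationError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return sample
    rng = as_rng(seed)
    f = 0.0
    while f <= 0:
        f = 1.0 + sigma * rng.standard_normal()
    return sample.replace(**{variable: sample.values(variable) * f})


def apply_change(
    change: ChangeModel, sample: Sample, source: PopulationSource, rng
) -> Sample:
    """Dispatch a :class:`ChangeModel` onto one sample."""
    if change.kind == "none":
        return sample
    if change.kind == "linear_growth":
        return apply_linear_growth(sample, change.variable, change.factor)
    if change.kind == "head_swelling":
        return apply_head_swelling(sample, change.factor)
    if change.kind == "filopodia_elimination":
        return apply_filopodia_elimination(
            sample,
            source,
            length_threshold=change.length_threshold,
            p_elim=change.elimination_probability,
            seed=rng,
            replacement_pool=change.replacement_pool,
        )
    if change.kind == "small_spine_growth":
        return apply_small_spine_growth(
            sample, area_threshold=change.area_threshold, factor=change.factor
        )
    if change.kind == "systematic_perturbation":
        return apply_systematic_perturbation(
            sample, change.variable, change.sigma, seed=rng
        )
    raise ConfigurationError(f"unknown change kind {change.kind!r}")
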