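"""One-dimensional Gaussian mixture fitting by expectation–maximisation.

Spine length distributions are heavy-tailed and can be parametrised as a
superposition of three Gaussian components, plausibly reflecting distinct
spine classes.  This module provides a small, transparent 1-D EM fitter whose
per-iteration log-likelihood trajectory is recorded, so the defining property
of EM — a non-decreasing log-likelihood — is observable and testable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, UndefinedValueError

__all__ = ["MixtureModel", "fit_length_mixture"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MixtureModel:
    """A k-component univariate Gaussian mixture, components sorted by mean."""

    weights: tuple
    means: tuple
    sds: tuple
    log_likelihood: float = float("nan")
    loglik_trajectory: tuple = field(default=(), repr=False)
    n_iter: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        mu = np.asarray(self.means, float)
        sd = np.asarray(self.sds, float)
        if not (w.shape == mu.shape == sd.shape) or w.ndim != 1 or w.size < 1:
            raise ConfigurationError("weights, means and sds must be equal-length 1-D")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture weights must sum to 1, got {w.sum()!r}")
        if np.any(sd <= 0):
            raise ConfigurationError("mixture sds must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        comp = _component_logpdf(x, np.asarray(self.means), np.asarray(self.sds))
        return logsumexp(comp + np.log(self.weights), axis=1)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        which = rng.choice(self.k, size=n, p=np.asarray(self.weights))
        return rng.normal(np.asarray(self.means)[which], np.asarray(self.sds)[which])


def _component_logpdf(x, means, sds):
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z**2 - np.log(sds)[None, :] - 0.5 * _LOG_2PI


def _sorted_model(w, mu, sd, ll, traj, it) -> MixtureModel:
    order = np.argsort(mu)
    return MixtureModel(
        tuple(w[order]), tuple(mu[order]), tuple(sd[order]),
        log_likelihood=float(ll), loglik_trajectory=tuple(traj), n_iter=it,
    )


def fit_length_mixture(
    lengths, k: int = 3, *, max_iter: int = 500, tol: float = 1e-8
) -> MixtureModel:
    """Maximum-likelihood fit of a k-component Gaussian mixture to 1-D data.

    Initialisation is deterministic (quantile-spaced means, pooled sd), so a
    given data set always yields the same fit.  Component sds are floored at
    1e-6 of the data range to prevent degenerate spikes.

    Raises
    ------
    ConvergenceError
        if the relative log-likelihood improvement has not fallen below
        ``tol`` within ``max_iter`` iterations; the error carries the
        best-so-far model in ``.best``.
    UndefinedValueError
        for degenerate data (fewer than 10·k points or zero variance).
    """
    x = np.asarray(lengths, dtype=float).ravel()
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if x.size < 10 * k:
        raise UndefinedValueError(
            f"mixture fit needs at least {10 * k} values for k={k}, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise UndefinedValueError("mixture fit is undefined for constant data")

    # deterministic moment/quantile initialisation
    qs = (2 * np.arange(k) + 1) / (2 * k)
    mu = np.quantile(x, qs)
    sd = np.full(k, max(np.std(x) / max(k, 1), 1e-12))
    w = np.full(k, 1.0 / k)
    sd_floor = 1e-6 * np.ptp(x)

    traj = []
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        # E-step
        logp = _component_logpdf(x, mu, sd) + np.log(w)[None, :]
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        traj.append(ll)
        resp = np.exp(logp - norm[:, None])

        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, sd_floor**2))

        if ll - prev_ll <= tol * max(1.0, abs(ll)) and it > 1:
            return _sorted_model(w, mu, sd, ll, traj, it)
        prev_ll = ll

    best = _sorted_model(w, mu, sd, traj[-1], traj, max_iter)
    raise ConvergenceError(
        f"EM did not converge within {max_iter} iterations "
        f"(last log-likelihood {traj[-1]:.6g})",
        best=best,
        trajectory=tuple(traj),
    )
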