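"""Ex-Gaussian distribution primitives.

The ex-Gaussian — the convolution of a Gaussian N(mu, sigma^2) with an
exponential of mean tau — is the standard parametric description of
positively skewed reaction-time distributions.  All race-model runners
(stop, go-match, go-mismatch) use it for their finish times.

The log-density and log-survival functions below are evaluated in log
space so that they remain usable deep in the tails and for small tau,
where the textbook formulas overflow.  They are vectorised over both the
evaluation points and the parameters (numpy broadcasting), because the
hierarchical sampler evaluates them for all chains at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "ExGauss",
    "exgauss_logpdf",
    "exgauss_pdf",
    "exgauss_logsf",
    "exgauss_sf",
    "exgauss_cdf",
    "exgauss_rvs",
]

_SQRT2 = np.sqrt(2.0)
_LOG2 = np.log(2.0)


# -- fast kernels (no validation / explicit broadcasting); used by the
#    likelihood hot path where parameters are already bound-checked --------

def _logpdf(t, mu, sigma, tau):
    z = (t - mu) / sigma
    u = (sigma / tau - z) / _SQRT2
    with np.errstate(over="ignore"):
        log_erfcx = np.where(
            u < -20.0, _LOG2 + u * u, np.log(special.erfcx(np.minimum(u, 1e8)))
        )
    return -np.log(2.0 * tau) + log_erfcx - 0.5 * z * z


def _logsf(t, mu, sigma, tau):
    z = (t - mu) / sigma
    term_gauss = special.log_ndtr(-z)
    term_exp = 0.5 * (sigma / tau) ** 2 - (t - mu) / tau + special.log_ndtr(z - sigma / tau)
    return np.logaddexp(term_gauss, term_exp)


def _sf(t, mu, sigma, tau):
    """Survival in linear space; cheaper than exp(_logsf) where only the
    probability (not its log) is needed."""
    z = (t - mu) / sigma
    w = 0.5 * (sigma / tau) ** 2 - (t - mu) / tau + special.log_ndtr(z - sigma / tau)
    return np.minimum(special.ndtr(-z) + np.exp(np.minimum(w, 0.0)), 1.0)


def _validate_scales(sigma, tau) -> None:
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be > 0")


def exgauss_logpdf(t, mu, sigma, tau):
    """Log-density of the ex-Gaussian at ``t``.

    Uses the scaled complementary error function (erfcx) so the Gaussian
    and exponential factors never overflow; the deep exponential tail
    (erfcx argument below -20) switches to the exact asymptotic form.
    """
    _validate_scales(sigma, tau)
    t, mu, sigma, tau = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, mu, sigma, tau))
    )
    return _logpdf(t, mu, sigma, tau)


def exgauss_pdf(t, mu, sigma, tau):
    """Ex-Gaussian density."""
    return np.exp(exgauss_logpdf(t, mu, sigma, tau))


def exgauss_logsf(t, mu, sigma, tau):
    """Log survival function log P(T > t).

    S(t) = Phi(-z) + exp(sigma^2/(2 tau^2) - (t - mu)/tau) * Phi(z - sigma/tau)
    with z = (t - mu)/sigma; both terms are positive, so the sum is a
    numerically safe logaddexp of two log terms.
    """
    _validate_scales(sigma, tau)
    t, mu, sigma, tau = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, mu, sigma, tau))
    )
    return _logsf(t, mu, sigma, tau)


def exgauss_sf(t, mu, sigma, tau):
    """Survival function P(T > t)."""
    return np.exp(exgauss_logsf(t, mu, sigma, tau))


def exgauss_cdf(t, mu, sigma, tau):
    """Cumulative distribution function."""
    return -np.expm1(exgauss_logsf(t, mu, sigma, tau))


def exgauss_rvs(mu, sigma, tau, size, rng: np.random.Generator):
    """Draw finish times: Gaussian component plus exponential component."""
    _validate_scales(sigma, tau)
    return mu + sigma * rng.standard_normal(size) + tau * rng.standard_exponential(size)


@dataclass(frozen=True)
class ExGauss:
    """Ex-Gaussian finish-time distribution with Gaussian (mu, sigma) and
    exponential mean tau; the distribution mean is mu + tau."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu, self.sigma, self.tau]).all():
            raise ValueError("ExGauss parameters must be finite")
        _validate_scales(self.sigma, self.tau)

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    def logpdf(self, t):
        return exgauss_logpdf(t, self.mu, self.sigma, self.tau)

    def pdf(self, t):
        return exgauss_pdf(t, self.mu, self.sigma, self.tau)

    def logsf(self, t):
        return exgauss_logsf(t, self.mu, self.sigma, self.tau)

    def sf(self, t):
        return exgauss_sf(t, self.mu, self.sigma, self.tau)

    def cdf(self, t):
        return exgauss_cdf(t, self.mu, self.sigma, self.tau)

    def rvs(self, size, rng: np.random.Generator):
        return exgauss_rvs(self.mu, self.sigma, self.tau, size, rng)
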