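"""Generalized gamma distribution in the location-scale-shape parameterization.

The family used for distributional (normative) regression of regional brain
volumes: a positive response ``y`` with location ``mu`` (same units as ``y``),
relative dispersion ``sigma`` and power shape ``nu``.  Writing
``theta = 1 / (sigma**2 * nu**2)`` and ``z = (y / mu)**nu``, the model is
``theta * z ~ Gamma(theta, 1)``.  Special cases:

* ``nu = 1, sigma = 1`` -> exponential with mean ``mu``;
* ``nu -> 0``           -> lognormal with log-scale median ``mu`` and
  log-standard-deviation ``sigma``.

The lognormal limit is used whenever ``|nu| < NU_EPS`` to keep the likelihood
and its derivatives finite.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["gg_pdf", "gg_cdf", "gg_quantile", "gg_logpdf", "gg_rvs", "NU_EPS"]

# below this |nu| the distribution is numerically indistinguishable from the
# lognormal limit and the gamma-based formulas lose precision
NU_EPS = 1e-4


def _validate(mu, sigma):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return mu, sigma


def gg_logpdf(y, mu, sigma, nu):
    """Log-density of the generalized gamma at ``y > 0``."""
    mu, sigma = _validate(mu, sigma)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    nu = float(nu)
    logy, logmu = np.log(y), np.log(mu)
    if abs(nu) < NU_EPS:
        r = (logy - logmu) / sigma
        return -logy - np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * r * r
    theta = 1.0 / (sigma**2 * nu**2)
    u = nu * (logy - logmu)
    # log f = log|nu| + theta*log(theta) + theta*u - theta*e^u - log y - lgamma(theta)
    return (
        np.log(abs(nu))
        + theta * np.log(theta)
        + theta * u
        - theta * np.exp(u)
        - logy
        - special.gammaln(theta)
    )


def gg_pdf(y, mu, sigma, nu):
    """Density of the generalized gamma at ``y > 0``."""
    return np.exp(gg_logpdf(y, mu, sigma, nu))


def gg_cdf(y, mu, sigma, nu):
    """Distribution function ``P(Y <= y)``."""
    mu, sigma = _validate(mu, sigma)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    nu = float(nu)
    if abs(nu) < NU_EPS:
        return stats.norm.cdf((np.log(y) - np.log(mu)) / sigma)
    theta = 1.0 / (sigma**2 * nu**2)
    u = theta * np.exp(nu * (np.log(y) - np.log(mu)))
    # upper-tail form for nu < 0 keeps precision in the far tails
    return special.gammainc(theta, u) if nu > 0 else special.gammaincc(theta, u)


def gg_quantile(p, mu, sigma, nu):
    """Exact inverse of :func:`gg_cdf` for ``p`` in (0, 1)."""
    mu, sigma = _validate(mu, sigma)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    nu = float(nu)
    if abs(nu) < NU_EPS:
        return np.exp(np.log(mu) + sigma * stats.norm.ppf(p))
    theta = 1.0 / (sigma**2 * nu**2)
    u = special.gammaincinv(theta, p) if nu > 0 else special.gammainccinv(theta, p)
    return mu * np.exp(np.log(u / theta) / nu)


def gg_rvs(mu, sigma, nu, size=None, rng=None):
    """Random draws; broadcasting over the parameters.

    Parameters
    ----------
    rng : numpy.random.Generator, optional
        Source of randomness (a fresh default generator when omitted).
    """
    mu, sigma = _validate(mu, sigma)
    rng = np.random.default_rng(rng)
    nu = float(nu)
    if size is None:
        size = np.broadcast(mu, sigma).shape or None
    if abs(nu) < NU_EPS:
        return np.exp(np.log(mu) + sigma * rng.standard_normal(size))
    theta = 1.0 / (sigma**2 * nu**2)
    g = rng.gamma(shape=np.broadcast_to(theta, size if size else ()), size=size)
    return mu * (g / theta) ** (1.0 / nu)
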