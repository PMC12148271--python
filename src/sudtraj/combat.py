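"""Empirical-Bayes scanner/batch harmonization (ComBat).

Location/scale batch adjustment for multi-feature measurements (here the 24
regional volumes): each feature is standardized on a covariate fit, per-batch
means and variances are shrunk toward pooled priors estimated across features,
the shrunken batch effects are removed and the data are transformed back.
Covariate-associated variation is preserved by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CombatHarmonizer", "combat_adjust"]


def _aprior(delta_hat):
    m, s2 = np.mean(delta_hat), np.var(delta_hat, ddof=1) if len(delta_hat) > 1 else 0.0
    if s2 <= 0:
        return 2.0
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = np.mean(delta_hat), np.var(delta_hat, ddof=1) if len(delta_hat) > 1 else 0.0
    if s2 <= 0:
        return m
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative solution for the parametric EB batch effect posteriors."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ssq = np.sum((sdat - g_new[None, :]) ** 2, axis=0)
        d_new = _postvar(ssq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class CombatHarmonizer(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch adjustment of a feature matrix.

    Parameters
    ----------
    parametric : bool
        Use the parametric (normal / inverse-gamma) priors; the only mode
        implemented.
    shrink : bool
        Empirical-Bayes shrinkage of the per-batch effects toward the pooled
        priors (default).  ``shrink=False`` removes the raw per-batch
        location/scale exactly, which makes the adjustment idempotent at the
        cost of not borrowing strength across features.

    Attributes
    ----------
    batches_ : ndarray
        Unique batch labels seen in fit.
    gamma_star_, delta_star_ : ndarray (n_batches, n_features)
        Shrunken batch location / scale effects on the standardized scale.
    """

    def __init__(self, parametric: bool = True, shrink: bool = True):
        self.parametric = parametric
        self.shrink = shrink

    def fit(self, X, y=None, *, batches, covariates=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 1:
            X = X[:, None]
        batches = np.asarray(batches)
        if len(batches) != X.shape[0]:
            raise ValueError("batches length must match the number of rows")
        self.batches_ = np.unique(batches)
        n, p = X.shape
        counts = np.array([np.sum(batches == b) for b in self.batches_])
        if np.any(counts < 2):
            raise ValueError("every batch needs at least 2 records")

        # design: batch indicators + covariates (no global intercept)
        B = np.column_stack([(batches == b).astype(float) for b in self.batches_])
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            C = C - C.mean(axis=0)  # keep batch columns interpretable as means
        else:
            C = np.empty((n, 0))
        design = np.column_stack([B, C])
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        nb = len(self.batches_)
        gamma_hat = beta[:nb]                      # (nb, p) batch means
        self.beta_cov_ = beta[nb:]                 # covariate effects
        grand = (counts / n) @ gamma_hat           # (p,) weighted grand mean

        fitted_cov = C @ self.beta_cov_
        resid = X - fitted_cov - B @ gamma_hat
        pooled_var = np.sum(resid**2, axis=0) / n
        pooled_var = np.maximum(pooled_var, 1e-24)
        self.grand_mean_ = grand
        self.pooled_std_ = np.sqrt(pooled_var)

        sdat = (X - fitted_cov - grand[None, :]) / self.pooled_std_[None, :]
        gamma_hat_s = gamma_hat - grand[None, :]
        gamma_hat_s /= self.pooled_std_[None, :]

        delta_hat = np.empty((nb, p))
        for i, b in enumerate(self.batches_):
            sub = sdat[batches == b] - gamma_hat_s[i][None, :]
            # denominator matches the pooled variance so that exact-mode
            # adjustment leaves unit within-batch variance (idempotence)
            delta_hat[i] = np.sum(sub**2, axis=0) / counts[i]
        self._mean_only_ = delta_hat.min(axis=1) <= 1e-12
        if np.any(self._mean_only_):
            warnings.warn(
                "batch with zero within-batch variance: mean-only adjustment used"
            )
        delta_hat = np.maximum(delta_hat, 1e-12)

        gamma_star = np.empty_like(gamma_hat_s)
        delta_star = np.empty_like(delta_hat)
        for i, b in enumerate(self.batches_):
            if self.shrink and p >= 2 and not self._mean_only_[i]:
                g_bar = np.mean(gamma_hat_s[i])
                t2 = np.var(gamma_hat_s[i], ddof=1) if p > 1 else 1.0
                t2 = max(t2, 1e-12)
                a, b_pr = _aprior(delta_hat[i]), _bprior(delta_hat[i])
                g, d = _it_sol(
                    sdat[batches == b], gamma_hat_s[i], delta_hat[i], g_bar, t2, a, b_pr
                )
            elif self.shrink:
                g, d = gamma_hat_s[i], np.ones(p)
            else:
                g, d = gamma_hat_s[i], delta_hat[i]
            gamma_star[i], delta_star[i] = g, d
            if self._mean_only_[i]:
                delta_star[i] = 1.0
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.n_features_in_ = p
        return self

    def transform(self, X, *, batches, covariates=None):
        check_is_fitted(self, "gamma_star_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        batches = np.asarray(batches)
        if len(self.batches_) == 1:
            return X.copy()
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != X.shape[0]:
                C = C.T
            C = C - C.mean(axis=0)
            fitted_cov = C @ self.beta_cov_
        else:
            fitted_cov = 0.0
        out = np.empty_like(X)
        for i, b in enumerate(self.batches_):
            mask = batches == b
            s = (X[mask] - fitted_cov[mask] if covariates is not None else X[mask])
            s = (s - self.grand_mean_[None, :]) / self.pooled_std_[None, :]
            s = (s - self.gamma_star_[i][None, :]) / np.sqrt(self.delta_star_[i])[None, :]
            out[mask] = (
                s * self.pooled_std_[None, :]
                + self.grand_mean_[None, :]
                + (fitted_cov[mask] if covariates is not None else 0.0)
            )
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).transform(X, **kwargs)


def combat_adjust(volumes, batches, covariates=None, shrink=True):
    """Batch-adjust a (records x features) volume matrix.

    Thin functional wrapper over :class:`CombatHarmonizer`; a single batch is
    returned unchanged.
    """
    volumes = np.atleast_2d(np.asarray(volumes, dtype=float))
    if len(np.unique(np.asarray(batches))) == 1:
        return volumes.copy()
    est = CombatHarmonizer(shrink=shrink)
    return est.fit_transform(volumes, batches=batches, covariates=covariates)
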