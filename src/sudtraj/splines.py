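"""Natural cubic regression splines and group trajectory fits.

The group-level volume trajectories are ordinary least-squares fits on a
natural cubic spline basis of age with K interior knots (default K=3, placed
at the 25/50/75% age quantiles of the fitted group).  Pointwise standard
errors come from the coefficient covariance: ``se(a) = sqrt(x(a)' V x(a))``.
Natural splines are linear beyond the boundary knots, which keeps mild
extrapolation stable; grid spans outside the observed age range are flagged.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["natural_spline_basis", "NaturalSplineTrajectory"]


def natural_spline_basis(x, knots, boundary):
    """Natural cubic spline design matrix (with intercept).

    Truncated-power natural basis: columns ``1, x`` plus one nonlinear column
    per interior knot, built so the function is linear beyond the boundary
    knots.

    Parameters
    ----------
    x : array-like
    knots : sequence
        Interior knot locations.
    boundary : (low, high)
        Boundary knot pair.

    Returns
    -------
    ndarray of shape (n, 2 + len(knots))
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(boundary[0]), float(boundary[1])
    xi = np.sort(np.asarray(list(knots) + [hi], dtype=float))
    if xi[0] <= lo:
        raise ValueError("interior knots must lie inside the boundary knots")

    def d(k):
        return (np.maximum(x - k, 0) ** 3 - np.maximum(x - xi[-1], 0) ** 3) / (
            xi[-1] - k
        )

    d_last = d(xi[-2]) if len(xi) >= 2 else 0.0
    cols = [np.ones_like(x), x]
    for k in xi[:-2]:
        cols.append(d(k) - d_last)
    # the last interior knot's own column uses the boundary-low reference
    if len(xi) >= 2:
        cols.append(d(lo) - d_last)
    return np.column_stack(cols)


class NaturalSplineTrajectory(BaseEstimator, RegressorMixin):
    """Least-squares natural cubic spline of a response on age.

    Parameters
    ----------
    n_knots : int
        Number of interior knots (placed at equally spaced quantiles of the
        training ages: 25/50/75% for the default 3).

    Attributes
    ----------
    coef_ : ndarray
        Spline coefficients.
    cov_ : ndarray
        Coefficient covariance ``sigma^2 (X'X)^{-1}``.
    knots_, boundary_ : fitted knot locations.
    age_range_ : (min, max) of the training ages.
    """

    def __init__(self, n_knots: int = 3):
        self.n_knots = n_knots

    def _basis(self, age):
        return natural_spline_basis(age, self.knots_, self.boundary_)

    def fit(self, age, y, sample_weight=None):
        age = np.asarray(age, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if age.size != y.size:
            raise ValueError("age and y must have the same length")
        if np.ptp(age) == 0:
            raise ValueError("all ages identical: trajectory is unidentifiable")
        qs = np.linspace(0, 100, self.n_knots + 2)[1:-1]
        knots = np.percentile(age, qs)
        lo, hi = age.min(), age.max()
        # nudge coincident knots off the boundary
        eps = 1e-8 * max(hi - lo, 1.0)
        knots = np.clip(knots, lo + eps, hi - eps)
        self.knots_ = np.unique(knots)
        self.boundary_ = (lo - eps, hi + eps)
        self.age_range_ = (lo, hi)
        X = self._basis(age)
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float))
            Xw, yw = X * w[:, None], y * w
        else:
            Xw, yw = X, y
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ coef
        dof = max(X.shape[0] - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        self.coef_ = coef
        self.cov_ = sigma2 * xtx_inv
        self.sigma2_ = sigma2
        self.n_obs_ = X.shape[0]
        return self

    def predict(self, age):
        check_is_fitted(self, "coef_")
        return self._basis(np.asarray(age, dtype=float).ravel()) @ self.coef_

    def predict_se(self, age):
        """Pointwise standard error of the fitted mean."""
        check_is_fitted(self, "coef_")
        X = self._basis(np.asarray(age, dtype=float).ravel())
        var = np.einsum("ij,jk,ik->i", X, self.cov_, X)
        return np.sqrt(np.maximum(var, 1e-300))

    def in_range(self, age):
        """Boolean mask of ages inside the observed training range."""
        age = np.asarray(age, dtype=float).ravel()
        lo, hi = self.age_range_
        return (age >= lo) & (age <= hi)
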