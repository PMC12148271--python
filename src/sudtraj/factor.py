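"""Principal-axis factor analysis with varimax rotation and regression scores.

Shared by the behavioral common-factor extraction (eigenvalue > 1 retention on
the instrument correlation matrix) and the atlas term-map factor analysis
(explained-variance > 1% retention).  Sign convention: each factor is flipped
so the variable with the largest absolute loading loads positively, which
makes scores reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["varimax", "principal_axis_factors", "regression_scores"]


def varimax(loadings, gamma=1.0, max_iter=200, tol=1e-8):
    """Varimax rotation; returns (rotated loadings, orthogonal rotation matrix)."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (gamma / p) * Lr @ np.diag(np.sum(Lr**2, axis=0)))
        )
        R = u @ vt
        var_new = np.sum(s)
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return L @ R, R


def _fix_signs(loadings):
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs[None, :], signs


def principal_axis_factors(corr, n_factors=None, retain="kaiser", var_threshold=0.01,
                           n_iter=50, tol=1e-6, rotate=True):
    """Principal-axis extraction from a correlation matrix.

    Parameters
    ----------
    corr : (p, p) correlation matrix (symmetrised; ridge-regularised with a
        warning if not positive semi-definite).
    n_factors : int, optional
        Fixed number of factors; otherwise chosen by ``retain``.
    retain : {"kaiser", "variance"}
        "kaiser": eigenvalues of the correlation matrix > 1 (strict);
        "variance": factors explaining > ``var_threshold`` of total variance.
    n_iter : communality-iteration count for principal-axis refinement.

    Returns
    -------
    dict with "loadings" (p, k), "eigenvalues" (p,), "rotation" (k, k),
    "explained_variance" (k,) fraction of total variance per rotated factor.
    """
    R = np.asarray(corr, dtype=float)
    R = 0.5 * (R + R.T)
    p = R.shape[0]
    eigvals = np.linalg.eigvalsh(R)[::-1]
    if eigvals[-1] < -1e-8:
        warnings.warn("correlation matrix not PSD: ridge regularisation applied")
        R = R + (1e-6 - eigvals[-1]) * np.eye(p)
        eigvals = np.linalg.eigvalsh(R)[::-1]

    if n_factors is None:
        if retain == "kaiser":
            n_factors = int(np.sum(eigvals > 1.0))
        elif retain == "variance":
            n_factors = int(np.sum(eigvals / p > var_threshold))
        else:
            raise ValueError(f"unknown retention rule {retain!r}")
    if n_factors == 0:
        return {
            "loadings": np.zeros((p, 0)),
            "eigenvalues": eigvals,
            "rotation": np.zeros((0, 0)),
            "explained_variance": np.zeros(0),
        }
    n_factors = min(n_factors, p)

    # principal-axis: iterate communalities on the reduced correlation matrix
    h2 = 1.0 - 1.0 / np.maximum(np.diag(np.linalg.pinv(R)), 1.0)  # SMC start
    for _ in range(n_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, v = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[order], 0.0, None)
        L = v[:, order] * np.sqrt(lam)[None, :]
        h2_new = np.clip(np.sum(L**2, axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    if rotate and n_factors > 1:
        L, Rot = varimax(L)
    else:
        Rot = np.eye(n_factors)
    L, _ = _fix_signs(L)
    explained = np.sum(L**2, axis=0) / p
    order = np.argsort(explained)[::-1]
    return {
        "loadings": L[:, order],
        "eigenvalues": eigvals,
        "rotation": Rot,
        "explained_variance": explained[order],
    }


def regression_scores(data_std, corr, loadings):
    """Thompson regression-method factor scores for standardized data.

    ``scores = Z R^{-1} L``; rescaled to unit sample variance.
    """
    Z = np.asarray(data_std, dtype=float)
    L = np.asarray(loadings, dtype=float)
    if L.shape[1] == 0:
        return np.zeros((Z.shape[0], 0))
    # pseudoinverse: the correlation matrix can be rank-deficient when there
    # are fewer observations than variables
    W = np.linalg.pinv(np.asarray(corr, dtype=float), rcond=1e-8) @ L
    scores = Z @ W
    sd = scores.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (scores - scores.mean(axis=0)) / sd
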