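"""Atlas term-map factor analysis and spin-permutation association.

Term-by-parcel meta-analytic maps are factor-analyzed (varimax, factors
explaining > 1% of variance retained; per factor, terms kept when their
loading exceeds 0.2 AND reaches the factor's median absolute loading).  The
resulting factor maps are regressed against the SUD-HC differential z map at
half-year age steps; significance comes from a spin-permutation null: random
3D rotations of the parcel centroids with nearest-centroid reassignment of
the factor map, which preserves the map's spatial autocorrelation.  Parcels
without spherical coordinates (subcortex) fall back to a value-permutation
null and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divergence import bh_fdr
from .factor import principal_axis_factors, regression_scores

__all__ = [
    "AtlasFactorSet",
    "atlas_factor_analysis",
    "differential_map_at_age",
    "random_rotations",
    "spin_correlation",
    "age_profile",
    "moran_statistic",
    "SpinResult",
]

ATLAS_AGES = np.round(np.arange(8.0, 70.0 + 1e-9, 0.5), 1)  # 125 half-year steps


@dataclass
class AtlasFactorSet:
    """Retained loadings, factor maps and bookkeeping from the term FA."""

    loadings: pd.DataFrame          # terms x factors (rotated, unmasked)
    retained_mask: pd.DataFrame     # terms x factors, bool
    factor_maps: pd.DataFrame       # parcels x factors
    explained_variance: pd.Series   # per retained factor


def atlas_factor_analysis(term_maps, var_threshold=0.01, loading_threshold=0.2):
    """Factor-analyze a term x parcel matrix into factor-level maps.

    Parameters
    ----------
    term_maps : DataFrame (terms as rows, parcels as columns) or array.
    var_threshold : retain factors explaining more than this fraction of the
        total variance.
    loading_threshold : terms retained per factor when |loading| exceeds this
        AND is at or above the factor's median absolute loading.

    Returns
    -------
    :class:`AtlasFactorSet`
    """
    df = pd.DataFrame(term_maps)
    terms = list(df.index)
    if df.shape[0] < 2 or df.shape[1] < 24:
        raise ValueError("need at least 2 terms and 24 parcels")
    X = df.to_numpy(dtype=float).T  # parcels are observations, terms variables
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    corr = np.corrcoef(Xs.T)
    if np.linalg.matrix_rank(corr) == 1:
        warnings.warn("rank-1 term matrix: single factor returned")
    res = principal_axis_factors(corr, retain="variance",
                                 var_threshold=var_threshold)
    L = res["loadings"]
    kept_factors = []
    masks = []
    for f in range(L.shape[1]):
        absload = np.abs(L[:, f])
        med = np.median(absload)
        mask = (absload > loading_threshold) & (absload >= med)
        if not mask.any():
            warnings.warn(f"factor {f}: no term passes the loading filters; dropped")
            continue
        kept_factors.append(f)
        masks.append(mask)
    L = L[:, kept_factors]
    mask_mat = np.column_stack(masks) if masks else np.zeros((len(terms), 0), bool)
    expl = res["explained_variance"][kept_factors]

    # factor maps: per-factor regression scores over parcels from the
    # retained terms only (the full correlation can be rank-deficient when
    # parcels are fewer than terms)
    if L.shape[1]:
        cols = []
        for f in range(L.shape[1]):
            sel = mask_mat[:, f]
            sub = regression_scores(Xs[:, sel], corr[np.ix_(sel, sel)],
                                    L[sel, f][:, None])
            cols.append(sub[:, 0])
        maps = np.column_stack(cols)
    else:
        maps = np.zeros((Xs.shape[0], 0))
    names = [f"factor_{i+1}" for i in range(L.shape[1])]
    return AtlasFactorSet(
        loadings=pd.DataFrame(L, index=terms, columns=names),
        retained_mask=pd.DataFrame(mask_mat, index=terms, columns=names),
        factor_maps=pd.DataFrame(maps, index=df.columns, columns=names),
        explained_variance=pd.Series(expl, index=names),
    )


def differential_map_at_age(grids, age):
    """SUD-HC differential z across regions at one age.

    Parameters
    ----------
    grids : dict region -> :class:`~sudtraj.divergence.DivergenceGrid`
    age : target age (snapped to the nearest 0.05y grid point if off-grid).

    Returns
    -------
    Series region -> z(age).
    """
    return pd.Series({roi: g.z_at(age) for roi, g in grids.items()})


def random_rotations(n, rng):
    """Uniform random 3D rotation matrices (det +1) from Gaussian triples."""
    A = rng.standard_normal((n, 3, 3))
    Q, R = np.linalg.qr(A)
    # make the decomposition unique (positive diagonal of R), then fix det
    diag = np.sign(np.einsum("nii->ni", R))
    diag[diag == 0] = 1.0
    Q = Q * diag[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1.0
    return Q


def moran_statistic(values, centroids, k=5):
    """Moran-type spatial autocorrelation on a k-nearest-neighbor graph.

    ``I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
    with binary weights on the k nearest neighbors (by geodesic distance).
    """
    x = np.asarray(values, dtype=float).ravel()
    P = np.asarray(centroids, dtype=float)
    n = len(x)
    cosd = np.clip(P @ P.T, -1.0, 1.0)
    d = np.arccos(cosd)
    np.fill_diagonal(d, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        W[i, np.argsort(d[i])[:k]] = 1.0
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return 0.0
    return float(n / W.sum() * (xc @ W @ xc) / denom)


@dataclass
class SpinResult:
    """Observed association of one factor map with a z map plus its spin null."""

    observed_r2: float
    null_r2: np.ndarray
    p_spin: float
    slope: float


def _r2(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx = x - x.mean()
    vy = y - y.mean()
    denom = np.sqrt((vx @ vx) * (vy @ vy))
    if denom <= 0:
        return 0.0, 0.0
    r = float(vx @ vy / denom)
    slope = float(vx @ vy / (vx @ vx)) if vx @ vx > 0 else 0.0
    return r * r, slope


def spin_correlation(factor_map, z_map, centroids, n_spins=1000, seed=0,
                     spin_mask=None):
    """Spin-permutation test of a factor map against a differential z map.

    Observed R^2 from the univariate regression of the z map on the factor
    map.  Null: the centroids are randomly rotated and each parcel takes the
    factor value of its nearest rotated centroid (duplicates allowed); one-
    sided p with the +1 correction: ``p = (1 + #{null >= obs}) / (1 + n)``.

    Parameters
    ----------
    centroids : (p, 3) unit-sphere coordinates, rows matched to the maps.
    spin_mask : bool array, optional
        Parcels that participate in the rotation (default: all).  Parcels
        outside the mask (no spherical coordinates) are value-permuted
        instead.
    """
    f = np.asarray(factor_map, dtype=float).ravel()
    z = np.asarray(z_map, dtype=float).ravel()
    P = np.asarray(centroids, dtype=float)
    if P.shape != (len(f), 3):
        raise ValueError("centroids must be (n_parcels, 3) matched to the maps")
    norms = np.linalg.norm(P, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("centroids must lie on the unit sphere")
    if n_spins < 100:
        warnings.warn("fewer than 100 spins: p-values will be coarse")
    rng = np.random.default_rng(seed)
    if spin_mask is None:
        spin_mask = np.ones(len(f), dtype=bool)
    spin_mask = np.asarray(spin_mask, dtype=bool)

    obs_r2, slope = _r2(f, z)
    R = random_rotations(n_spins, rng)
    Ps = P[spin_mask]
    rotated = np.einsum("sij,pj->spi", R, Ps)  # (n_spins, p_spin, 3)
    # nearest original centroid for each rotated position
    d = rotated @ Ps.T                          # cosine similarity
    nearest = np.argmax(d, axis=2)              # (n_spins, p_spin)
    null_r2 = np.empty(n_spins)
    f_spun = np.empty_like(f)
    perm_idx = np.where(~spin_mask)[0]
    for s in range(n_spins):
        f_spun[spin_mask] = f[spin_mask][nearest[s]]
        if perm_idx.size:
            f_spun[perm_idx] = f[perm_idx][rng.permutation(perm_idx.size)]
        null_r2[s], _ = _r2(f_spun, z)
    p = (1.0 + np.sum(null_r2 >= obs_r2)) / (1.0 + n_spins)
    return SpinResult(observed_r2=obs_r2, null_r2=null_r2, p_spin=p, slope=slope)


def age_profile(factor_set, grids, centroids, ages=None, n_spins=1000, seed=0,
                spin_mask=None, alpha=0.05):
    """R^2(age) curves of every factor map against the differential z maps.

    One spin test per factor x age, BH-FDR across ages within each factor,
    and a peak-age summary (age of maximal R^2).

    Returns
    -------
    (long DataFrame with factor, age, r2, p_spin, q; dict factor -> peak age)
    """
    ages = ATLAS_AGES if ages is None else np.asarray(ages, dtype=float)
    rows = []
    rng = np.random.default_rng(seed)
    for fname in factor_set.factor_maps.columns:
        fmap = factor_set.factor_maps[fname].to_numpy()
        pvals, r2s = [], []
        for age in ages:
            zmap = differential_map_at_age(grids, age).to_numpy()
            res = spin_correlation(
                fmap, zmap, centroids, n_spins=n_spins,
                seed=int(rng.integers(2**31)), spin_mask=spin_mask,
            )
            pvals.append(res.p_spin)
            r2s.append(res.observed_r2)
        qvals = bh_fdr(np.array(pvals))
        for age, r2v, pv, qv in zip(ages, r2s, pvals, qvals):
            rows.append({"factor": fname, "age": age, "r2": r2v,
                         "p_spin": pv, "q": qv})
    df = pd.DataFrame(rows)
    peaks = {
        f: float(sub.loc[sub["r2"].idxmax(), "age"])
        for f, sub in df.groupby("factor")
    }
    return df, peaks
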