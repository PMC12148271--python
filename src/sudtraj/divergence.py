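"""Group trajectory divergence on a fine age grid, with validation machinery.

Pipeline: covariate adjustment (sex, handedness, study, pooled across groups)
-> per-group natural-spline trajectories -> pointwise two-sided z tests on a
0.05-year grid from 8y to 70y -> Benjamini-Hochberg FDR within each region ->
maximal runs of q < alpha reported as significant age windows.  Longitudinal
change-rate regression, inverse-variance meta-analysis, Spearman consistency
between discovery and validation z-curves, and hierarchical clustering of
centile patterns support the validation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .splines import NaturalSplineTrajectory, natural_spline_basis

__all__ = [
    "AGE_GRID",
    "adjust_covariates",
    "fit_group_trajectory",
    "divergence_grid",
    "bh_fdr",
    "significance_trajectory",
    "longitudinal_change_rate",
    "ivw_meta",
    "consistency_correlation",
    "cluster_centile_patterns",
    "DivergenceGrid",
]

AGE_LO, AGE_HI, AGE_STEP = 8.0, 70.0, 0.05
AGE_GRID = np.round(np.arange(0, round((AGE_HI - AGE_LO) / AGE_STEP) + 1) * AGE_STEP
                    + AGE_LO, 2)  # 1241 points, endpoints inclusive


def adjust_covariates(values, covariates):
    """Remove linear sex/handedness/study effects, pooled across groups.

    Parameters
    ----------
    values : array-like (n,)
    covariates : DataFrame or dict of array-like
        Columns are entered as given; string/object columns are dummy-coded
        (first level dropped).

    Returns
    -------
    ndarray: residuals plus the grand mean (location preserved).
    """
    y = np.asarray(values, dtype=float).ravel()
    cov = pd.DataFrame(covariates)
    cols = [np.ones(len(y))]
    for name in cov.columns:
        col = cov[name]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            if dummies.size:
                cols.append(dummies)
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient covariate design: aliased columns dropped")
        q, r, piv = _qr_pivot(X)
        X = X[:, piv[:rank]]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + y.mean()


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def fit_group_trajectory(values, ages, n_knots=3):
    """Fit one group's age trajectory (natural cubic spline, K interior knots)."""
    values = np.asarray(values, dtype=float).ravel()
    ages = np.asarray(ages, dtype=float).ravel()
    if values.size < 30:
        raise ValueError("need at least 30 records to fit a group trajectory")
    return NaturalSplineTrajectory(n_knots=n_knots).fit(ages, values)


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up q-values (capped at 1, order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DivergenceGrid:
    """Per-region age-grid comparison of the two group trajectories."""

    roi: str
    ages: np.ndarray
    m_hc: np.ndarray
    se_hc: np.ndarray
    m_sud: np.ndarray
    se_sud: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    in_range: np.ndarray
    windows: list = field(default_factory=list)

    def to_frame(self):
        return pd.DataFrame(
            {
                "roi": self.roi,
                "age": self.ages,
                "m_hc": self.m_hc,
                "se_hc": self.se_hc,
                "m_sud": self.m_sud,
                "se_sud": self.se_sud,
                "z": self.z,
                "p": self.p,
                "q": self.q,
                "in_range": self.in_range,
            }
        )

    def z_at(self, age):
        """z at a grid age (off-grid ages snap to the nearest grid point)."""
        idx = int(np.argmin(np.abs(self.ages - age)))
        return float(self.z[idx])


def _windows_from_mask(ages, mask):
    """Maximal runs of True as closed [start, end] age intervals."""
    windows = []
    in_run = False
    for i, flag in enumerate(mask):
        if flag and not in_run:
            start = ages[i]
            in_run = True
        elif not flag and in_run:
            windows.append((float(start), float(ages[i - 1])))
            in_run = False
    if in_run:
        windows.append((float(start), float(ages[-1])))
    return windows


def divergence_grid(traj_sud, traj_hc, roi="roi", alpha=0.05, ages=None):
    """Compare two fitted trajectories pointwise on the 0.05-year age grid.

    ``z(a) = (m_sud - m_hc) / sqrt(se_sud^2 + se_hc^2)``; two-sided normal
    p-values; BH-FDR across the grid points within the region; significant
    windows are maximal runs of ``q < alpha`` restricted to ages covered by
    both groups' observed ranges.
    """
    if traj_sud is None or traj_hc is None:
        raise ValueError("both group trajectories are required")
    ages = AGE_GRID if ages is None else np.asarray(ages, dtype=float)
    m_sud, se_sud = traj_sud.predict(ages), traj_sud.predict_se(ages)
    m_hc, se_hc = traj_hc.predict(ages), traj_hc.predict_se(ages)
    z = (m_sud - m_hc) / np.sqrt(se_sud**2 + se_hc**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    in_range = traj_sud.in_range(ages) & traj_hc.in_range(ages)
    windows = _windows_from_mask(ages, (q < alpha) & in_range)
    return DivergenceGrid(
        roi=roi, ages=ages, m_hc=m_hc, se_hc=se_hc, m_sud=m_sud, se_sud=se_sud,
        z=z, p=p, q=q, in_range=in_range, windows=windows,
    )


def significance_trajectory(grid, alpha=0.05, n_knots=20):
    """Smoothed signed significance curve and its alpha-level crossings.

    A cubic-spline smoother is fitted to ``sign(z) * -log10(q)``; ages where
    the smoothed curve crosses ``+/- -log10(alpha)`` are the reported window
    edges.
    """
    s = np.sign(grid.z) * (-np.log10(np.clip(grid.q, 1e-300, 1.0)))
    ages = grid.ages
    if np.allclose(s, 0.0):
        return ages, np.zeros_like(s), []
    nk = min(n_knots, max(len(ages) // 10, 4))
    traj = NaturalSplineTrajectory(n_knots=nk).fit(ages, s)
    smooth = traj.predict(ages)
    level = -np.log10(alpha)
    above = np.abs(smooth) > level
    crossings = [float(ages[i]) for i in range(1, len(ages)) if above[i] != above[i - 1]]
    return ages, smooth, crossings


def longitudinal_change_rate(scans, roi, group_col="group", case_label="SUD"):
    """Group difference in annualised volume change, adjusting for age and sex.

    Per participant with >= 2 visits: slope = (last - first volume) /
    (last - first age); then OLS ``slope ~ group + age + sex`` with the
    baseline age.  Returns (coef, se, p) for the group term (case vs control).
    """
    df = scans.sort_values(["pid", "age"])
    rows = []
    for pid, sub in df.groupby("pid"):
        if len(sub) < 2:
            continue
        d_age = sub["age"].iloc[-1] - sub["age"].iloc[0]
        if d_age <= 0:
            continue
        rows.append(
            {
                "slope": (sub[roi].iloc[-1] - sub[roi].iloc[0]) / d_age,
                "group": float(sub[group_col].iloc[0] == case_label),
                "age": sub["age"].iloc[0],
                "sex": sub["sex"].iloc[0],
            }
        )
    if not rows:
        raise ValueError("no participants with follow-up visits")
    d = pd.DataFrame(rows)
    X = np.column_stack(
        [np.ones(len(d)), d["group"], d["age"], d["sex"].astype(float)]
    )
    y = d["slope"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(d) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[1]), float(se), float(p)


def ivw_meta(estimates, ses):
    """Inverse-variance weighted pooling: returns (pooled estimate, pooled SE)."""
    m = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if m.shape != s.shape:
        raise ValueError("estimates and ses must have the same length")
    if np.any(s < 0):
        raise ValueError("standard errors must be non-negative")
    if np.any(s == 0):
        # degenerate limit: an exact estimate dominates
        exact = m[s == 0]
        return float(exact[0]), 0.0
    w = s**-2.0
    return float(np.sum(w * m) / np.sum(w)), float(np.sum(w) ** -0.5)


def consistency_correlation(z_discovery, ages_discovery, z_validation, ages_validation):
    """Spearman correlation of two z-curves over their overlapping age span."""
    a1 = np.round(np.asarray(ages_discovery, dtype=float), 6)
    a2 = np.round(np.asarray(ages_validation, dtype=float), 6)
    common, i1, i2 = np.intersect1d(a1, a2, return_indices=True)
    if common.size < 3:
        return np.nan
    r, _ = stats.spearmanr(np.asarray(z_discovery)[i1], np.asarray(z_validation)[i2])
    return float(r)


def cluster_centile_patterns(centiles, n_clusters=None, cut_height=None):
    """Hierarchical clustering of regions by centile-pattern correlation.

    Parameters
    ----------
    centiles : DataFrame (participants x regions)
    n_clusters, cut_height : one of the two cut criteria (default: 2 clusters).

    Returns
    -------
    (labels, Z): dict region -> cluster id and the scipy linkage matrix.
    """
    df = pd.DataFrame(centiles)
    keep = [c for c in df.columns if df[c].std() > 0]
    dropped = [c for c in df.columns if c not in keep]
    if dropped:
        warnings.warn(f"constant centile columns dropped: {dropped}")
    df = df[keep]
    if df.shape[1] == 1:
        return {keep[0]: 1}, None
    corr = np.corrcoef(df.to_numpy().T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(Z, t=n_clusters or 2, criterion="maxclust")
    return dict(zip(keep, labels)), Z
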