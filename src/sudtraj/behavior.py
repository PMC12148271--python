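"""Behavioral and neurocognitive comparisons, common factors, brain-behavior.

Group comparisons are covariate-adjusted linear models (Cohen's d from the
adjusted mean difference over the pooled residual SD) with BH-FDR within
study and optional 1:1 down-sampling of the majority group; common
rule-breaking / impulsivity factors come from principal-axis factor analysis
(eigenvalue > 1 retention, varimax, regression scores); brain-behavior
associations are Pearson (or partial) correlations between factor scores and
region centiles with BH-FDR across regions; adolescent-study effect sizes
are pooled by Fisher-z inverse-variance meta-analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import bh_fdr
from .factor import principal_axis_factors, regression_scores

__all__ = [
    "group_compare",
    "interaction_model",
    "extract_common_factors",
    "brain_behavior_corr",
    "meta_effects",
]


def _adjusted_d(score, group, covariates):
    """Cohen's d, SE and p from the linear model score ~ group + covariates."""
    y = np.asarray(score, dtype=float)
    g = np.asarray(group, dtype=float)
    n = len(y)
    cols = [np.ones(n), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.append(C)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0:
        return np.nan, np.nan, np.nan
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    d = beta[1] / np.sqrt(sigma2)
    return float(d), float(p), float(se / np.sqrt(sigma2))


def group_compare(scores, groups, covariates=None, downsample=False, repeats=1000,
                  case_label="SUD", seed=0):
    """Per-score adjusted group comparison: Cohen's d, p and BH-FDR q.

    Parameters
    ----------
    scores : DataFrame (one column per instrument score).
    groups : array-like of group labels.
    downsample : subsample the majority controls 1:1 with the cases
        ``repeats`` times and report the median d and p.

    Returns
    -------
    DataFrame indexed by score name with columns d, p, q.
    """
    df = pd.DataFrame(scores)
    groups = np.asarray(groups)
    g = (groups == case_label).astype(float)
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    case_idx = np.where(g == 1)[0]
    ctrl_idx = np.where(g == 0)[0]
    out = {}
    for name in df.columns:
        y = df[name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if downsample and len(ctrl_idx) > len(case_idx):
            ds, ps = [], []
            for _ in range(repeats):
                sub_ctrl = rng.choice(ctrl_idx, size=len(case_idx), replace=False)
                idx = np.concatenate([case_idx, sub_ctrl])
                idx = idx[ok[idx]]
                C = None
                if covariates is not None:
                    C = np.atleast_2d(np.asarray(covariates, dtype=float))
                    if C.shape[0] != len(g):
                        C = C.T
                    C = C[idx]
                d, p, _ = _adjusted_d(y[idx], g[idx], C)
                ds.append(d)
                ps.append(p)
            out[name] = (float(np.nanmedian(ds)), float(np.nanmedian(ps)))
        else:
            C = None
            if covariates is not None:
                C = np.atleast_2d(np.asarray(covariates, dtype=float))
                if C.shape[0] != len(g):
                    C = C.T
                C = C[ok]
            d, p, _ = _adjusted_d(y[ok], g[ok], C)
            out[name] = (d, p)
    res = pd.DataFrame(out, index=["d", "p"]).T
    res["q"] = bh_fdr(np.nan_to_num(res["p"].to_numpy(), nan=1.0))
    res.loc[res["p"].isna(), "q"] = np.nan
    return res


def interaction_model(scores, groups, age, sex=None, hand=None, case_label="SUD"):
    """Age-by-group interaction: score ~ age + group + age*group (+ sex, hand).

    Returns (coefficient, SE, p) for the interaction term.
    """
    y = np.asarray(scores, dtype=float)
    g = (np.asarray(groups) == case_label).astype(float)
    a = np.asarray(age, dtype=float)
    if np.ptp(a) == 0:
        raise ValueError("age has no spread")
    cols = [np.ones(len(y)), a, g, a * g]
    for extra in (sex, hand):
        if extra is not None:
            cols.append(np.asarray(extra, dtype=float))
    X = np.column_stack(cols)
    cond = np.linalg.cond(X.T @ X)
    if cond > 1e12:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[3, 3])
    t = beta[3] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[3]), float(se), float(p)


def extract_common_factors(behavior, factor_labels=None):
    """Common rule-breaking / impulsivity factors from one study's instruments.

    Principal-axis factor analysis on the pairwise-complete instrument
    correlation matrix, eigenvalue > 1 retention (strict), varimax rotation,
    regression scores (unit variance).  Factors are labelled by the
    instrument carrying their maximal absolute loading, optionally mapped
    through ``factor_labels`` (instrument -> label, e.g. "rule_breaking").

    Returns
    -------
    dict with "scores" (DataFrame, one column per factor), "loadings",
    "eigenvalues", "n_factors".
    """
    df = pd.DataFrame(behavior)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 instruments")
    corr = df.corr(min_periods=2).to_numpy()
    if np.any(np.isnan(corr)):
        raise ValueError("pairwise-complete correlations not estimable")
    res = principal_axis_factors(corr, retain="kaiser")
    k = res["loadings"].shape[1]
    if k == 0:
        return {"scores": pd.DataFrame(index=df.index), "loadings": res["loadings"],
                "eigenvalues": res["eigenvalues"], "n_factors": 0}
    Z = (df - df.mean()) / df.std(ddof=0)
    Z = Z.fillna(0.0).to_numpy()
    scores = regression_scores(Z, corr, res["loadings"])
    names = []
    for f in range(k):
        top = df.columns[int(np.argmax(np.abs(res["loadings"][:, f])))]
        label = (factor_labels or {}).get(top, str(top))
        # avoid duplicated names
        name, i = label, 2
        while name in names:
            name = f"{label}_{i}"
            i += 1
        names.append(name)
    return {
        "scores": pd.DataFrame(scores, index=df.index, columns=names),
        "loadings": pd.DataFrame(res["loadings"], index=df.columns, columns=names),
        "eigenvalues": res["eigenvalues"],
        "n_factors": k,
    }


def brain_behavior_corr(factor_scores, centiles, partial=None):
    """Per-region correlation between a factor score and region centiles.

    Pearson correlation (partial correlation given the conditioning score
    when ``partial`` is supplied), two-sided p, BH-FDR across regions.

    Parameters
    ----------
    factor_scores : Series indexed by pid.
    centiles : wide DataFrame (index pid, columns regions).
    partial : optional Series indexed by pid (the other factor).

    Returns
    -------
    DataFrame indexed by region with columns r, p, q (and degenerate flag).
    """
    s = pd.Series(factor_scores).dropna()
    C = pd.DataFrame(centiles)
    common = s.index.intersection(C.index)
    if partial is not None:
        partial = pd.Series(partial)
        common = common.intersection(partial.dropna().index)
    if len(common) < 10:
        raise ValueError("fewer than 10 matched participants")
    s = s.loc[common].to_numpy(dtype=float)
    rows = {}
    for roi in C.columns:
        x = C.loc[common, roi].to_numpy(dtype=float)
        degenerate = False
        if partial is not None:
            w = partial.loc[common].to_numpy(dtype=float)
            if np.corrcoef(w, s)[0, 1] > 1 - 1e-12:
                degenerate = True
                r, p = 0.0, 1.0
            else:
                r, p = _partial_corr(s, x, w)
        else:
            r, p = stats.pearsonr(s, x)
        rows[roi] = (float(r), float(p), degenerate)
    res = pd.DataFrame(rows, index=["r", "p", "degenerate"]).T
    res["q"] = bh_fdr(res["p"].to_numpy(dtype=float))
    return res


def _partial_corr(a, b, control):
    Z = np.column_stack([np.ones(len(a)), control])
    Q, _ = np.linalg.qr(Z)
    ra = a - Q @ (Q.T @ a)
    rb = b - Q @ (Q.T @ b)
    if ra.std() == 0 or rb.std() == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(ra, rb)[0, 1])
    n = len(a)
    dof = n - 3
    t = r * np.sqrt(dof / max(1e-12, 1 - r * r))
    p = 2 * stats.t.sf(abs(t), dof)
    return r, float(p)


def meta_effects(r_values, ns):
    """Fisher-z inverse-variance pooling of per-study correlations.

    Weights ``n - 3``; studies with ``n <= 3`` are excluded with a warning.
    Returns (pooled r, SE of the pooled Fisher z).
    """
    import warnings

    r = np.asarray(r_values, dtype=float)
    n = np.asarray(ns, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 studies")
    ok = n > 3
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} studies with n <= 3 excluded")
    r, n = r[ok], n[ok]
    z = np.arctanh(r)
    w = n - 3
    z_pool = np.sum(w * z) / np.sum(w)
    se = np.sum(w) ** -0.5
    return float(np.tanh(z_pool)), float(se)
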