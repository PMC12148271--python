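"""Genotype QC, association testing, brain score, pruning and condFDR.

The genetics arm: standard per-variant QC (missingness, call rate, MAF,
Hardy-Weinberg), longitudinal case/control collapsing, covariate-adjusted
Wald association (batched Newton logistic for binary phenotypes, closed-form
OLS for continuous ones), the wGMV brain score (region centiles weighted by
the SUD-HC differential z), greedy sliding-window LD pruning, polygenic
scoring, PGS-based genetic correlation, and the empirical conditional /
conjunctional FDR used to localize SNPs shared between SUD liability and the
brain score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "qc_filter",
    "collapse_case_control",
    "snp_association",
    "wgmv_weights",
    "compute_wgmv",
    "ld_prune",
    "pgs_score",
    "pgs_genetic_correlation",
    "cond_fdr",
    "conj_fdr",
    "gene_pgs_compare",
]


# -- QC ---------------------------------------------------------------------

def qc_filter(dosages, variant_map, max_sample_missing=0.10, min_call_rate=0.95,
              min_maf=0.01, hwe_alpha=1e-10):
    """Sample and variant quality control.

    Parameters
    ----------
    dosages : (n_samples, m_variants) array with entries {0, 1, 2, nan}.
    variant_map : DataFrame with columns chrom, pos, id (rows match columns).

    Returns
    -------
    (filtered dosages, filtered variant map, sample keep-mask, report dict)
    """
    G = np.asarray(dosages, dtype=float)
    vm = pd.DataFrame(variant_map).reset_index(drop=True)
    n, m = G.shape
    sample_missing = np.mean(np.isnan(G), axis=1)
    keep_samples = sample_missing <= max_sample_missing
    G = G[keep_samples]

    miss = np.isnan(G)
    call_rate = 1.0 - miss.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    # HWE chi-square (1 df) on genotype counts
    hwe_p = np.ones(m)
    for j in range(m):
        g = G[:, j]
        g = g[~np.isnan(g)]
        if g.size == 0:
            hwe_p[j] = 1.0
            continue
        n0, n1, n2 = np.sum(g == 0), np.sum(g == 1), np.sum(g == 2)
        tot = n0 + n1 + n2
        p = (2 * n2 + n1) / (2 * tot)
        exp = np.array([tot * (1 - p) ** 2, 2 * tot * p * (1 - p), tot * p**2])
        obs = np.array([n0, n1, n2])
        if np.any(exp < 1e-12):
            hwe_p[j] = 1.0
            continue
        chi2 = np.sum((obs - exp) ** 2 / exp)
        hwe_p[j] = stats.chi2.sf(chi2, df=1)

    keep_variants = (
        (call_rate >= min_call_rate)
        & (maf >= min_maf)
        & np.isfinite(maf)
        & (hwe_p >= hwe_alpha)
    )
    report = {
        "n_samples_in": n,
        "n_samples_dropped": int(np.sum(~keep_samples)),
        "n_variants_in": m,
        "dropped_call_rate": int(np.sum(call_rate < min_call_rate)),
        "dropped_maf": int(np.sum(~((maf >= min_maf) & np.isfinite(maf)))),
        "dropped_hwe": int(np.sum(hwe_p < hwe_alpha)),
        "n_variants_kept": int(np.sum(keep_variants)),
    }
    if report["n_variants_kept"] == 0 or G.shape[0] == 0:
        raise ValueError(f"QC removed everything: {report}")
    return G[:, keep_variants], vm.loc[keep_variants].reset_index(drop=True), \
        keep_samples, report


def collapse_case_control(visit_labels, case_label="SUD"):
    """Binary phenotype from longitudinal visit labels.

    A participant is a case iff the number of visits labelled as SUD is
    strictly greater than half the total visits.

    Parameters
    ----------
    visit_labels : DataFrame with columns pid, group (one row per visit).

    Returns
    -------
    Series indexed by pid with values 1 (case) / 0 (control).
    """
    df = pd.DataFrame(visit_labels)
    counts = df.groupby("pid")["group"].agg(
        n_sud=lambda g: int(np.sum(g == case_label)), n_total="size"
    )
    return (counts["n_sud"] > counts["n_total"] / 2.0).astype(int)


# -- association ------------------------------------------------------------

def _batched_logistic_wald(G, y, C, max_iter=30, tol=1e-8):
    """Wald statistics for y ~ C + g_j, one Newton solve per variant, batched.

    Returns beta, se arrays (nan where the fit is degenerate/separated).
    """
    n, m = G.shape
    k = C.shape[1]
    beta = np.zeros((m, k + 1))
    # warm start all variants from the covariate-only fit
    from numpy.linalg import LinAlgError

    b0 = np.zeros(k)
    for _ in range(50):
        eta = C @ b0
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = C.T @ (y - p)
        H = (C * w[:, None]).T @ C
        try:
            step = np.linalg.solve(H, grad)
        except LinAlgError:
            break
        b0 = b0 + step
        if np.max(np.abs(step)) < tol:
            break
    beta[:, :k] = b0

    X = np.empty((m, n, k + 1))
    X[:, :, :k] = C[None, :, :]
    X[:, :, k] = G.T
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        Xa, Ba = X[active], beta[active]
        eta = np.einsum("mnk,mk->mn", Xa, Ba)
        eta = np.clip(eta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = np.einsum("mnk,mn->mk", Xa, y[None, :] - p)
        H = np.einsum("mnk,mn,mnj->mkj", Xa, w, Xa)
        H = H + 1e-10 * np.eye(k + 1)[None, :, :]
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        beta[active] = Ba + step
        done = np.max(np.abs(step), axis=1) < tol
        idx = np.where(active)[0]
        active[idx[done]] = False

    eta = np.einsum("mnk,mk->mn", X, beta)
    eta = np.clip(eta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    H = np.einsum("mnk,mn,mnj->mkj", X, w, X)
    se = np.full(m, np.nan)
    b = beta[:, k]
    for j in range(m):
        try:
            cov = np.linalg.inv(H[j])
            se[j] = np.sqrt(cov[k, k])
        except np.linalg.LinAlgError:
            pass
    # flag separation / blow-ups
    bad = ~np.isfinite(se) | (se > 1e3) | ~np.isfinite(b) | (np.abs(b) > 30)
    b = np.where(bad, np.nan, b)
    se = np.where(bad, np.nan, se)
    return b, se


def _batched_linear_wald(G, y, C):
    """Closed-form OLS Wald per variant with shared covariates.

    Residualizes y and each g_j on C (Frisch-Waugh), then the slope of the
    residual regression with the exact OLS degrees of freedom.
    """
    n, m = G.shape
    k = C.shape[1]
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gg = np.sum(G_r**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G_r.T @ y_r) / gg
    rss = np.sum(y_r**2) - beta**2 * gg
    dof = n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0) / dof / gg)
    bad = (gg <= 1e-12) | ~np.isfinite(beta)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    return beta, se, dof


def snp_association(dosages, phenotype, covariates=None, variant_map=None):
    """Per-variant covariate-adjusted Wald association.

    Logistic regression for a binary phenotype, linear regression otherwise.
    Missing dosages are mean-imputed per variant.  Degenerate variants
    (constant dosage, separation) are flagged with missing statistics.

    Returns a GWAS table: id, chrom, pos, a1, a2, beta, se, z, p, n.
    """
    G = np.asarray(dosages, dtype=float).copy()
    y = np.asarray(phenotype, dtype=float).ravel()
    n, m = G.shape
    if len(y) != n:
        raise ValueError("phenotype length must match dosage rows")
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        C = np.column_stack([np.ones(n), C])
    else:
        C = np.ones((n, 1))

    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        beta, se = _batched_logistic_wald(G, y, C)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        beta, se, dof = _batched_linear_wald(G, y, C)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        p = 2 * stats.t.sf(np.abs(z), dof)

    # constant dosage -> flagged missing
    const = np.nanstd(G, axis=0) <= 1e-12
    for arr in (beta, se, z, p):
        arr[const] = np.nan

    out = pd.DataFrame({"beta": beta, "se": se, "z": z, "p": p, "n": n})
    if variant_map is not None:
        vm = pd.DataFrame(variant_map).reset_index(drop=True)
        out = pd.concat([vm[[c for c in ("id", "chrom", "pos", "a1", "a2")
                             if c in vm]], out], axis=1)
    return out


# -- wGMV -------------------------------------------------------------------

def wgmv_weights(grids, age):
    """Default wGMV weights: the regional SUD-HC differential z at ``age``.

    ``grids`` maps region -> fitted divergence grid; a typical reference age
    is the mean age of the participant's study.  A GWAS-derived z vector can
    be passed to :func:`compute_wgmv` instead when the alternative weighting
    is wanted.
    """
    return pd.Series({roi: g.z_at(age) for roi, g in grids.items()})


def compute_wgmv(centiles, weights):
    """Weighted grey-matter-volume score per participant.

    Parameters
    ----------
    centiles : wide DataFrame (index pid, one column per region) or long
        DataFrame with columns pid, roi, centile.
    weights : dict or Series region -> weight (the SUD-HC differential z by
        default upstream).

    Returns
    -------
    Series pid -> score ``sum_roi w_roi * centile_roi``; participants with a
    missing region centile are skipped with a warning.
    """
    df = pd.DataFrame(centiles)
    if {"pid", "roi", "centile"} <= set(df.columns):
        wide = df.pivot_table(index="pid", columns="roi", values="centile")
    else:
        wide = df
    w = pd.Series(weights, dtype=float)
    missing_rois = [r for r in w.index if r not in wide.columns]
    if missing_rois:
        raise ValueError(f"weights cover regions absent from centiles: {missing_rois}")
    sub = wide[w.index]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"{int((~complete).sum())} participants skipped "
                      "(missing centiles)")
    return (sub.loc[complete] * w).sum(axis=1)


# -- LD pruning -------------------------------------------------------------

def ld_prune(dosages, variant_map, window_kb=50, step=5, r2_threshold=0.1):
    """Greedy sliding-window pairwise LD pruning (indep-pairwise style).

    Within each window of ``window_kb`` kilobases, for any pair with dosage
    ``r^2`` above the threshold the variant with the lower MAF is removed
    (ties: the later position); the window slides by ``step`` variants.
    Deterministic.  Returns the retained variant indices (into the map).
    """
    G = np.asarray(dosages, dtype=float)
    vm = pd.DataFrame(variant_map).reset_index(drop=True)
    m = len(vm)
    if G.shape[1] != m:
        raise ValueError("dosage columns must match the variant map")
    for chrom, sub in vm.groupby("chrom"):
        if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    col_mean = np.nanmean(G, axis=0)
    Gi = np.where(np.isnan(G), col_mean[None, :], G)
    freq = col_mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    pos = vm["pos"].to_numpy()
    chrom = vm["chrom"].to_numpy()
    keep = np.ones(m, dtype=bool)

    sd = Gi.std(axis=0)
    window_bp = window_kb * 1000

    start = 0
    while start < m:
        idx = [j for j in range(start, m)
               if chrom[j] == chrom[start] and pos[j] - pos[start] <= window_bp
               and keep[j]]
        for a_i in range(len(idx)):
            i = idx[a_i]
            if not keep[i]:
                continue
            for b_i in range(a_i + 1, len(idx)):
                j = idx[b_i]
                if not keep[j]:
                    continue
                if sd[i] <= 1e-12 or sd[j] <= 1e-12:
                    continue
                r = np.corrcoef(Gi[:, i], Gi[:, j])[0, 1]
                if r * r > r2_threshold:
                    if maf[i] < maf[j]:
                        drop = i
                    elif maf[j] < maf[i]:
                        drop = j
                    else:
                        drop = max(i, j)  # tie -> later position
                    keep[drop] = False
                    if drop == i:
                        break
        start += step
    return np.where(keep)[0]


# -- PGS --------------------------------------------------------------------

def pgs_score(dosages, gwas_table, variant_map, pruned_idx=None):
    """Polygenic score: sum of effect-allele dosages times GWAS betas.

    Alleles are aligned on (id, a1, a2); swapped-allele variants have their
    dosage reversed (2 - g); unresolvable mismatches are dropped with a count
    in the second return value.  Missing dosages are mean-imputed.
    """
    G = np.asarray(dosages, dtype=float)
    vm = pd.DataFrame(variant_map).reset_index(drop=True)
    gt = pd.DataFrame(gwas_table)
    if pruned_idx is not None:
        vm = vm.iloc[pruned_idx].reset_index(drop=True)
        G = G[:, np.asarray(pruned_idx)]
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean[None, :], G)

    score = np.zeros(G.shape[0])
    dropped = 0
    weights = gt.set_index("id")
    for j, row in vm.iterrows():
        if row["id"] not in weights.index:
            dropped += 1
            continue
        w = weights.loc[row["id"]]
        beta = float(w["beta"])
        if not np.isfinite(beta):
            continue
        if "a1" in vm.columns and "a1" in weights.columns:
            if row["a1"] == w["a1"] and row["a2"] == w["a2"]:
                g = G[:, j]
            elif row["a1"] == w["a2"] and row["a2"] == w["a1"]:
                g = 2.0 - G[:, j]
            else:
                dropped += 1
                continue
        else:
            g = G[:, j]
        score += g * beta
    return pd.Series(score), dropped


def pgs_genetic_correlation(pgs, target, covariates=None):
    """Standardized PGS-target regression: (std slope, incremental R^2, p).

    The uncorrected PGS-based estimate of cross-trait genetic correlation
    (flagged ``uncorrected``); covariates enter the model linearly.
    """
    x = np.asarray(pgs, dtype=float).ravel()
    y = np.asarray(target, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    if x.std() == 0:
        raise ValueError("constant PGS")
    xs = (x - x.mean()) / x.std()
    n = len(y)
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        C = np.column_stack([np.ones(n), C])
    else:
        C = np.ones((n, 1))
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    x_r = xs - Q @ (Q.T @ xs)
    gg = float(x_r @ x_r)
    beta = float(x_r @ y_r) / gg
    rss0 = float(y_r @ y_r)
    rss1 = rss0 - beta**2 * gg
    dof = n - C.shape[1] - 1
    se = np.sqrt(rss1 / dof / gg)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), dof)
    r2_inc = (rss0 - rss1) / rss0 if rss0 > 0 else 0.0
    y_sd = np.sqrt(rss0 / max(n - C.shape[1], 1))
    std_slope = beta / y_sd if y_sd > 0 else np.nan
    return {
        "slope_std": float(std_slope),
        "r2": float(r2_inc),
        "p": float(p),
        "uncorrected": True,
    }


# -- conditional / conjunctional FDR ---------------------------------------

def cond_fdr(p1, p2):
    """Pointwise empirical conditional FDR of trait 1 given trait 2.

    ``cFDR(p1 | p2) = p1 * #{P2 <= p2} / #{P1 <= p1 and P2 <= p2}`` evaluated
    at each variant's own pair, capped at 1.  Empty conditioning subsets give
    cFDR 1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p1 and p2 must be matched")
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p1)
    out = np.ones(m)
    for i in range(m):
        cond = p2 <= p2[i]
        denom = np.sum(cond & (p1 <= p1[i]))
        if denom == 0:
            out[i] = 1.0
        else:
            out[i] = min(1.0, p1[i] * np.sum(cond) / denom)
    return out


def conj_fdr(cfdr_1given2, cfdr_2given1, alpha=0.05, variant_map=None,
             dosages=None, window_kb=50, r2_threshold=0.1):
    """Conjunctional FDR: elementwise max of the two conditional FDRs.

    Returns (conjfdr array, lead-variant indices with conjFDR < alpha).  With
    a variant map (and optionally dosages), significant variants are clumped
    to one lead per LD neighborhood: best conjFDR first, neighbors within the
    window (and with r^2 above threshold, when dosages are given) absorbed.
    """
    c1 = np.asarray(cfdr_1given2, dtype=float)
    c2 = np.asarray(cfdr_2given1, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("mismatched cfdr vectors")
    conj = np.maximum(c1, c2)
    sig = np.where(conj < alpha)[0]
    if variant_map is None or sig.size == 0:
        return conj, list(sig)
    vm = pd.DataFrame(variant_map).reset_index(drop=True)
    order = sig[np.argsort(conj[sig], kind="stable")]
    leads, absorbed = [], set()
    G = np.asarray(dosages, dtype=float) if dosages is not None else None
    for i in order:
        if i in absorbed:
            continue
        leads.append(int(i))
        for j in sig:
            if j == i or j in absorbed:
                continue
            same_chrom = vm["chrom"].iloc[i] == vm["chrom"].iloc[j]
            close = abs(vm["pos"].iloc[i] - vm["pos"].iloc[j]) <= window_kb * 1000
            if same_chrom and close:
                if G is not None:
                    r = np.corrcoef(G[:, i], G[:, j])[0, 1]
                    if r * r <= r2_threshold:
                        continue
                absorbed.add(int(j))
    return conj, leads


def gene_pgs_compare(pgs, groups, case_label="SUD", min_n=10):
    """Two-sided t-test of a gene-level PGS between groups: (Cohen's d, p)."""
    pgs = np.asarray(pgs, dtype=float)
    groups = np.asarray(groups)
    a = pgs[groups == case_label]
    b = pgs[groups != case_label]
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"need at least {min_n} per group")
    t, p = stats.ttest_ind(a, b)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else np.nan
    return float(d), float(p)
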