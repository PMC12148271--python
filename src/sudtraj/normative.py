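"""Generalized-gamma normative modeling of regional brain volumes.

Workflow: outlier QC (4-IQR rule per region) -> scanner harmonization
(:mod:`sudtraj.combat`) -> one cross-sectional visit per participant
(frequency-inverse sampling) -> per-region generalized-gamma fit with
fractional-polynomial age effects on the log-location and log-dispersion,
sex/handedness terms, optional study offsets, BIC model selection -> centile
scoring of any scan against the fitted normative distribution.

Model: ``log mu = FP(age) b + sex + handedness [+ study offsets]``,
``log sigma = FP(age) g``, constant shape ``nu``.  The BIC search runs over
the FP degree of the location basis (1..max_degree), the FP degree of the
dispersion basis, and study-offset inclusion; within a degree the power
multiset is chosen by a fast least-squares screen on the log scale before
the full likelihood fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fp import fp_basis, fp_power_sets
from .gg import NU_EPS, gg_cdf, gg_logpdf

__all__ = [
    "qc_exclude_outliers",
    "sample_one_visit",
    "GGNormativeModel",
    "fit_normative",
    "score_centiles",
]

CENTILE_CLIP = (1e-7, 1.0 - 1e-7)


def qc_exclude_outliers(scans, roi_cols, k=4.0):
    """Drop scans with any regional volume beyond ``k`` IQRs of the quartiles.

    A scan is excluded when, for ANY region, its volume lies outside
    ``[Q1 - k*IQR, Q3 + k*IQR]``.  Returns (retained scans, per-region
    exclusion counts).
    """
    df = pd.DataFrame(scans)
    if len(df) < 8:
        raise ValueError("need at least 8 records to form quartiles")
    keep = np.ones(len(df), dtype=bool)
    report = {}
    for roi in roi_cols:
        v = df[roi].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        bad = (v < q1 - k * iqr) | (v > q3 + k * iqr)
        report[roi] = int(bad.sum())
        keep &= ~bad
    if not keep.any():
        raise ValueError("outlier rule excluded every record")
    return df.loc[keep].reset_index(drop=True), report


def sample_one_visit(scans, seed=0, bin_width=1.0):
    """One cross-sectional visit per participant, inverse-frequency weighted.

    For participants with multiple visits, one visit is sampled with
    probability proportional to the reciprocal of the pooled age-bin frequency
    of that visit's age (bins of ``bin_width`` years), normalized within the
    participant.  Deterministic under ``seed``.
    """
    df = pd.DataFrame(scans)
    rng = np.random.default_rng(seed)
    bins = np.floor(df["age"].to_numpy(dtype=float) / bin_width).astype(int)
    counts = pd.Series(bins).value_counts()
    freq = counts.reindex(bins).to_numpy(dtype=float)
    if np.any(freq <= 0) or np.any(~np.isfinite(freq)):
        warnings.warn("empty age bin encountered: uniform fallback")
        freq = np.where(np.isfinite(freq) & (freq > 0), freq, 1.0)
    inv = 1.0 / freq
    df = df.assign(_w=inv)
    out_idx = []
    for _, sub in df.groupby("pid", sort=False):
        if len(sub) == 1:
            out_idx.append(sub.index[0])
            continue
        w = sub["_w"].to_numpy()
        w = w / w.sum()
        out_idx.append(rng.choice(sub.index.to_numpy(), p=w))
    out = df.loc[sorted(out_idx)].drop(columns="_w").reset_index(drop=True)
    return out


def _design(age, sex, hand, study, powers_mu, powers_sigma, study_offsets):
    Xmu_cols = [np.ones(len(age)), *fp_basis(age, powers_mu).T,
                np.asarray(sex, float), np.asarray(hand, float)]
    study_levels = []
    if study_offsets:
        study = np.asarray(study)
        study_levels = sorted(set(study))[1:]  # first level is the reference
        for s in study_levels:
            Xmu_cols.append((study == s).astype(float))
    Xmu = np.column_stack(Xmu_cols)
    Xsig = np.column_stack([np.ones(len(age)), *fp_basis(age, powers_sigma).T])
    return Xmu, Xsig, study_levels


def _negloglik(params, y_log, y, Xmu, Xsig):
    kmu = Xmu.shape[1]
    ksig = Xsig.shape[1]
    beta, gamma, nu = params[:kmu], params[kmu:kmu + ksig], params[-1]
    logmu = Xmu @ beta
    logsig = np.clip(Xsig @ gamma, -20, 5)
    sigma = np.exp(logsig)
    if abs(nu) < NU_EPS:
        r = (y_log - logmu) / sigma
        ll = -y_log - logsig - 0.5 * np.log(2 * np.pi) - 0.5 * r * r
    else:
        theta = 1.0 / (sigma**2 * nu**2)
        u = nu * (y_log - logmu)
        u = np.clip(u, -500, 500)
        from scipy.special import gammaln

        ll = (
            np.log(abs(nu))
            + theta * np.log(theta)
            + theta * u
            - theta * np.exp(u)
            - y_log
            - gammaln(theta)
        )
    val = -np.sum(ll)
    return val if np.isfinite(val) else 1e12


def _screen_powers(age, target, degree):
    """Best power multiset of a degree by OLS on the (log-scale) target."""
    best, best_rss = None, np.inf
    for powers in fp_power_sets(degree):
        X = np.column_stack([np.ones(len(age)), fp_basis(age, powers)])
        coef, res, rank, _ = np.linalg.lstsq(X, target, rcond=None)
        rss = float(res[0]) if res.size else float(np.sum((target - X @ coef) ** 2))
        if rank < X.shape[1]:
            continue
        if rss < best_rss - 1e-10:
            best, best_rss = powers, rss
    return best


class GGNormativeModel:
    """Per-region generalized-gamma normative model with BIC selection.

    Parameters
    ----------
    max_degree : int
        Largest FP degree searched for the location and dispersion bases.
    search_study_offsets : bool
        Whether study fixed offsets on the log-location compete in the BIC
        search (skipped automatically for single-study data).
    n_restarts : int
        Jittered restarts used when the primary optimisation fails.

    Fitted attributes (trailing underscore) include the selected power
    multisets, coefficient vectors, ``nu_``, ``bic_``, ``loglik_``,
    ``search_log_`` (one record per candidate), and ``converged_``.
    """

    def __init__(self, roi="roi", max_degree=3, search_study_offsets=True,
                 n_restarts=3, tol=1e-12):
        self.roi = roi
        self.max_degree = max_degree
        self.search_study_offsets = search_study_offsets
        self.n_restarts = n_restarts
        self.tol = tol

    def get_params(self, deep=True):
        return {
            "roi": self.roi,
            "max_degree": self.max_degree,
            "search_study_offsets": self.search_study_offsets,
            "n_restarts": self.n_restarts,
            "tol": self.tol,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def _fit_candidate(self, y, age, sex, hand, study, powers_mu, powers_sigma,
                       offsets, rng):
        Xmu, Xsig, levels = _design(age, sex, hand, study, powers_mu,
                                    powers_sigma, offsets)
        y_log = np.log(y)
        # warm start from least squares on the log scale
        beta0, *_ = np.linalg.lstsq(Xmu, y_log, rcond=None)
        resid = y_log - Xmu @ beta0
        with np.errstate(divide="ignore"):
            log_r2 = np.log(np.maximum(resid**2, 1e-12))
        gamma0, *_ = np.linalg.lstsq(Xsig, 0.5 * (log_r2 + 1.27), rcond=None)
        x0 = np.concatenate([beta0, gamma0, [0.5]])

        def objective(params):
            return _negloglik(params, y_log, y, Xmu, Xsig)

        best = None
        for attempt in range(self.n_restarts):
            start = x0 if attempt == 0 else x0 + 0.1 * rng.standard_normal(len(x0))
            res = optimize.minimize(
                objective, start, method="L-BFGS-B",
                options={"maxiter": 1000, "ftol": self.tol, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        k = len(x0)
        n = len(y)
        loglik = -best.fun
        bic = -2.0 * loglik + k * np.log(n)
        return {
            "powers_mu": powers_mu,
            "powers_sigma": powers_sigma,
            "study_offsets": offsets,
            "study_levels": levels,
            "params": best.x,
            "loglik": loglik,
            "bic": bic,
            "k": k,
            "converged": bool(best.success),
            "kmu": Xmu.shape[1],
            "ksig": Xsig.shape[1],
        }

    def fit(self, scans, volume_col=None, seed=0):
        """Fit on healthy-control, cross-sectional scans.

        ``scans`` needs columns age, sex, hand, study and the volume column
        (``volume_col`` defaults to ``self.roi``).
        """
        df = pd.DataFrame(scans)
        volume_col = volume_col or self.roi
        y = df[volume_col].to_numpy(dtype=float)
        if np.any(y <= 0):
            raise ValueError("volumes must be strictly positive")
        if len(df) < 50:
            raise ValueError("need at least 50 training records")
        age = df["age"].to_numpy(dtype=float)
        sex = df["sex"].to_numpy(dtype=float)
        hand = df["hand"].to_numpy(dtype=float)
        study = df["study"].to_numpy() if "study" in df else np.zeros(len(df))
        multi_study = len(set(study)) > 1 and self.search_study_offsets
        rng = np.random.default_rng(seed)

        y_log = np.log(y)
        powers_by_degree = {
            d: _screen_powers(age, y_log, d) for d in range(1, self.max_degree + 1)
        }
        # dispersion screen on the log absolute residual of the best mu screen
        Xd = np.column_stack(
            [np.ones(len(age)), fp_basis(age, powers_by_degree[self.max_degree])]
        )
        b, *_ = np.linalg.lstsq(Xd, y_log, rcond=None)
        log_r2 = np.log(np.maximum((y_log - Xd @ b) ** 2, 1e-12))
        sig_powers_by_degree = {
            d: _screen_powers(age, log_r2, d) for d in range(1, self.max_degree + 1)
        }

        self.search_log_ = []
        for d_mu in range(1, self.max_degree + 1):
            for d_sig in range(1, self.max_degree + 1):
                for offsets in ([False, True] if multi_study else [False]):
                    cand = self._fit_candidate(
                        y, age, sex, hand, study,
                        powers_by_degree[d_mu], sig_powers_by_degree[d_sig],
                        offsets, rng,
                    )
                    self.search_log_.append(cand)
        converged = [c for c in self.search_log_ if c["converged"]]
        pool = converged if converged else self.search_log_
        if not converged:
            raise RuntimeError(
                "no candidate model converged; attempted: "
                + ", ".join(str((c["powers_mu"], c["powers_sigma"],
                                 c["study_offsets"])) for c in self.search_log_)
            )
        best = min(pool, key=lambda c: c["bic"])
        self._select(best, df, volume_col)
        return self

    def _select(self, cand, df, volume_col):
        self.powers_mu_ = cand["powers_mu"]
        self.powers_sigma_ = cand["powers_sigma"]
        self.study_offsets_ = cand["study_offsets"]
        self.study_levels_ = cand["study_levels"]
        kmu, ksig = cand["kmu"], cand["ksig"]
        self.beta_ = cand["params"][:kmu]
        self.gamma_ = cand["params"][kmu:kmu + ksig]
        self.nu_ = float(cand["params"][-1])
        self.loglik_ = cand["loglik"]
        self.bic_ = cand["bic"]
        self.converged_ = cand["converged"]
        self.n_train_ = len(df)
        self.age_range_ = (df["age"].min(), df["age"].max())
        self.volume_col_ = volume_col

    # -- prediction --------------------------------------------------------
    def _mu_sigma(self, age, sex, hand, study=None):
        n = len(np.atleast_1d(age))
        study_arr = np.asarray(study) if study is not None else np.zeros(n)
        Xmu, Xsig, _ = _design(
            np.atleast_1d(age), np.atleast_1d(sex), np.atleast_1d(hand),
            study_arr, self.powers_mu_, self.powers_sigma_, False,
        )
        logmu = Xmu @ self.beta_[: Xmu.shape[1]]
        if self.study_offsets_ and study is not None:
            offs = dict(zip(self.study_levels_, self.beta_[Xmu.shape[1]:]))
            logmu = logmu + np.array([offs.get(s, 0.0) for s in study_arr])
        sigma = np.exp(np.clip(Xsig @ self.gamma_, -20, 5))
        return np.exp(logmu), sigma

    def predict_mu(self, age, sex=0, hand=0, study=None):
        age = np.atleast_1d(np.asarray(age, dtype=float))
        sex = np.broadcast_to(np.asarray(sex, float), age.shape)
        hand = np.broadcast_to(np.asarray(hand, float), age.shape)
        return self._mu_sigma(age, sex, hand, study)[0]

    def transform(self, scans, volume_col=None):
        """Centiles (and probit z) for each scan under the fitted model."""
        df = pd.DataFrame(scans)
        volume_col = volume_col or self.volume_col_
        mu, sigma = self._mu_sigma(
            df["age"].to_numpy(float), df["sex"].to_numpy(float),
            df["hand"].to_numpy(float),
            df["study"].to_numpy() if "study" in df else None,
        )
        cent = gg_cdf(df[volume_col].to_numpy(float), mu, sigma, self.nu_)
        cent = np.clip(cent, *CENTILE_CLIP)
        lo, hi = self.age_range_
        extrap = (df["age"].to_numpy(float) < lo) | (df["age"].to_numpy(float) > hi)
        out = pd.DataFrame(
            {
                "pid": df["pid"] if "pid" in df else np.arange(len(df)),
                "visit": df["visit"] if "visit" in df else 0,
                "roi": self.roi,
                "centile": cent,
                "z": stats.norm.ppf(cent),
                "extrapolated": extrap,
            }
        )
        return out

    def to_dict(self):
        return {
            "roi": self.roi,
            "powers_mu": list(self.powers_mu_),
            "powers_sigma": list(self.powers_sigma_),
            "study_offsets": bool(self.study_offsets_),
            "study_levels": [str(s) for s in self.study_levels_],
            "beta": self.beta_.tolist(),
            "gamma": self.gamma_.tolist(),
            "nu": self.nu_,
            "loglik": self.loglik_,
            "bic": self.bic_,
            "n_train": self.n_train_,
            "converged": self.converged_,
        }


def fit_normative(hc_scans, roi, max_degree=3, seed=0, **kwargs):
    """Fit the per-region normative model on HC-only cross-sectional scans."""
    return GGNormativeModel(roi=roi, max_degree=max_degree, **kwargs).fit(
        hc_scans, seed=seed
    )


def score_centiles(models, scans):
    """Score scans against a set of fitted per-region models.

    Parameters
    ----------
    models : dict roi -> fitted :class:`GGNormativeModel`
    scans : DataFrame with the covariates and one column per region.

    Returns
    -------
    Long-format DataFrame (pid, visit, roi, centile, z, extrapolated).
    """
    frames = [m.transform(scans) for m in models.values()]
    return pd.concat(frames, ignore_index=True)
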