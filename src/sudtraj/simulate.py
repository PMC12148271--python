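"""Synthetic multi-cohort lifespan datasets with known ground truth.

Emulates the structure of the pooled discovery cohorts: several studies with
their own age windows, sex ratios and scanners; 24 addiction-circuit regions
whose volumes follow a generalized-gamma distribution with an inverted-U
age trend; three temporal classes of SUD-HC offsets (early-decaying, mid-life
bump, late-increasing); latent rule-breaking and impulsivity factors loading
onto instrument scores; LD-blocked genotypes whose causal variants couple to
SUD liability and/or to regional centile shifts through shared latent
scores; longitudinal follow-up visits with an extra annual decline in SUD;
and spatially autocorrelated term maps on a sphere of parcels.

SUD liability is ``logistic(w_g * genetic burden + w_i * impulsivity +
age-prevalence offset)``; the age offset makes prevalence rise to a peak
around 25y and fall thereafter.  Every sampled latent quantity is recorded in
a :class:`GroundTruthManifest` so downstream stages can be tested against
truth without re-simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gg import gg_cdf

__all__ = [
    "StudySpec",
    "RoiSpec",
    "SimConfig",
    "GroundTruthManifest",
    "default_rois",
    "generate_cohort",
    "generate_genotypes",
    "generate_atlas",
    "generate_followup",
    "fibonacci_sphere",
    "write_dataset",
]


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class StudySpec:
    name: str
    age_low: float
    age_high: float
    n: int
    sex_ratio: float = 0.5
    n_scanners: int = 1


@dataclass(frozen=True)
class RoiSpec:
    name: str
    category: str           # early | mid | late
    hemisphere: str         # L | R
    base_volume: float      # mm^3 at the trajectory peak


_ROI_BASES = {
    "frontal_pole": (4000.0, "early"),
    "superior_frontal": (22000.0, "early"),
    "rostral_acc": (2600.0, "mid"),
    "caudal_acc": (2100.0, "early"),
    "medial_ofc": (5200.0, "late"),
    "lateral_ofc": (7600.0, "mid"),
    "insula": (6800.0, "mid"),
    "caudate": (3700.0, "early"),
    "putamen": (5500.0, "early"),
    "accumbens": (620.0, "late"),
    "amygdala": (1700.0, "late"),
    "hippocampus": (4300.0, "late"),
}


def default_rois():
    """The 24 bilateral addiction-circuit regions with temporal classes."""
    rois = []
    for name, (base, cat) in _ROI_BASES.items():
        for hemi in ("L", "R"):
            rois.append(RoiSpec(f"{name}_{hemi.lower()}", cat, hemi, base))
    return tuple(rois)


def _default_studies():
    return (
        StudySpec("abcd", 9.0, 11.5, 900, 0.52, 3),
        StudySpec("imagen", 14.0, 23.5, 500, 0.54, 4),
        StudySpec("hcp", 22.0, 37.0, 500, 0.46, 1),
        StudySpec("ukb", 45.0, 70.0, 1100, 0.47, 3),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int = 0
    studies: tuple = field(default_factory=_default_studies)
    rois: tuple = field(default_factory=default_rois)

    # generalized-gamma truth (shared trend; per-region intercept from rois)
    fp_powers_mu: tuple = (1.0, 2.0)
    beta_age: tuple = (0.06, -0.012)      # inverted U on log mu, peak ~25y
    beta_sex: float = 0.04                # males ~4% larger
    beta_hand: float = 0.0
    study_offset_sd: float = 0.0          # per-study offsets on log mu
    fp_powers_sigma: tuple = (1.0,)
    gamma0: float = float(np.log(0.09))   # ~9% relative dispersion
    gamma_age: tuple = (0.01,)
    nu: float = 0.8

    # scanner batch effects (multiplicative shift / residual scale, log space)
    batch_shift_sd: float = 0.02
    batch_scale_sd: float = 0.05

    # SUD-HC offsets per temporal class, amplitude in within-person SD units
    amp_early: float = -0.35
    amp_mid: float = 0.35
    amp_late: float = -0.45
    early_decay: float = 5.0              # e-folding years from age 8
    mid_center: float = 45.0
    mid_width: float = 12.0
    late_center: float = 52.0
    late_scale: float = 4.0

    # liability model
    w_genetic: float = 0.8
    w_impulsivity: float = 0.5
    prev_base: float = -1.4               # logit prevalence at the age peak
    prev_peak_age: float = 25.0
    prev_width: float = 25.0

    # behavioral truth
    behavior_loadings: tuple = (
        ("rule_breaking_score", "rule_breaking", 0.75),
        ("conduct_problems", "rule_breaking", 0.70),
        ("novelty_seeking", "rule_breaking", 0.60),
        ("sensation_seeking", "impulsivity", 0.75),
        ("delay_discounting", "impulsivity", 0.70),
        ("motor_impulsivity", "impulsivity", 0.60),
    )
    factor_corr: float = 0.15             # rule-breaking x impulsivity
    group_shift_rule_breaking: float = 0.3

    # genotype truth
    n_variants: int = 400
    block_len: int = 5
    block_rho: float = 0.45
    maf_range: tuple = (0.10, 0.45)
    n_causal_sud: int = 6                 # SUD-liability-only variants
    n_causal_brain: int = 6               # brain-centile-only variants
    n_causal_shared: int = 4              # variants coupled to both
    causal_tau: float = 0.35              # latent coupling per causal variant
    shared_frac: float = 0.5              # latent overlap of burden and brain score
    brain_effect_sd: float = 0.0          # kappa: centile shift per brain score SD
    brain_coupled_category: str = "mid"

    # atlas truth
    n_parcels: int = 24
    n_terms: int = 28
    n_atlas_factors: int = 7
    atlas_bandwidth: float = 0.6          # geodesic kernel bandwidth (radians)
    atlas_noise_sd: float = 0.15

    # follow-up
    followup_prob: tuple = (("abcd", 0.5, 2.0), ("imagen", 0.4, 5.0),
                            ("ukb", 0.15, 8.0))   # (study, revisit prob, interval)
    followup_within_sd: float = 0.03      # log-scale visit-to-visit noise
    slope_diff: float = -0.005            # extra SUD decline, fraction / year

    def __post_init__(self):
        for s in self.studies:
            if s.n <= 0:
                raise ValueError(f"study {s.name}: n must be positive")
            if s.age_low >= s.age_high:
                raise ValueError(f"study {s.name}: age_low must be < age_high")
        if not -1.0 < self.block_rho < 1.0:
            raise ValueError("block_rho must lie in (-1, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for r in self.rois:
            if r.category not in ("early", "mid", "late"):
                raise ValueError(f"unknown temporal class {r.category!r}")
        if self.atlas_bandwidth <= 0:
            raise ValueError("atlas_bandwidth must be positive")


@dataclass
class GroundTruthManifest:
    """Every sampled latent quantity, keyed by participant/variant/parcel."""

    config: SimConfig
    participants: pd.DataFrame        # latents, liability, group per pid
    roi_truth: dict                   # roi -> generative parameter dict
    true_logmu: pd.DataFrame | None = None   # per scan x roi true log-location
    normative_logmu: pd.DataFrame | None = None  # HC-normative surface (no
                                                 # SUD offset / genetic shift)
    true_sigma: pd.Series | None = None      # per scan true dispersion
    true_nu: pd.Series | None = None         # per scan true shape
    causal_variants: pd.DataFrame | None = None
    atlas_loadings: np.ndarray | None = None
    atlas_patterns: np.ndarray | None = None

    def true_centiles(self, scans, roi_cols):
        """Centiles of the generated volumes under the true per-scan model.

        The scanner batch effect is a shift/power transform on the log scale,
        under which the generalized gamma family is closed; the manifest
        records the post-batch (logmu, sigma, nu) per scan so these centiles
        are exactly Uniform(0,1) by construction.
        """
        nus = self.true_nu.to_numpy(float)
        sigmas = self.true_sigma.to_numpy(float)
        out = {}
        for roi in roi_cols:
            mus = np.exp(self.true_logmu[roi].to_numpy(float))
            vals = scans[roi].to_numpy(float)
            cent = np.empty(len(vals))
            for nu in np.unique(nus):
                mask = nus == nu
                cent[mask] = gg_cdf(vals[mask], mus[mask], sigmas[mask], nu)
            out[roi] = cent
        return pd.DataFrame(out, index=scans.index)

    def normative_centiles(self, scans, roi_cols):
        """Centiles against the healthy-population normative surface.

        Unlike :meth:`true_centiles`, the reference excludes the SUD offsets
        and the individual genetic brain shift, so deviations (the signal a
        fitted normative model would expose) remain in the centiles.
        """
        nus = self.true_nu.to_numpy(float)
        sigmas = self.true_sigma.to_numpy(float)
        out = {}
        for roi in roi_cols:
            mus = np.exp(self.normative_logmu[roi].to_numpy(float))
            vals = scans[roi].to_numpy(float)
            cent = np.empty(len(vals))
            for nu in np.unique(nus):
                mask = nus == nu
                cent[mask] = gg_cdf(vals[mask], mus[mask], sigmas[mask], nu)
            out[roi] = cent
        return pd.DataFrame(out, index=scans.index)


# --------------------------------------------------------------------------
# helpers

def _rngs(config, n_streams=6):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n_streams)]


def sud_offset(category, age, config):
    """SUD-HC offset (in SD units) for a temporal class at the given ages."""
    age = np.asarray(age, dtype=float)
    if category == "early":
        return config.amp_early * np.exp(-(age - 8.0) / config.early_decay)
    if category == "mid":
        return config.amp_mid * np.exp(-(((age - config.mid_center)
                                          / config.mid_width) ** 2))
    if category == "late":
        return config.amp_late / (
            1.0 + np.exp(-(age - config.late_center) / config.late_scale)
        )
    raise ValueError(f"unknown temporal class {category!r}")


def prevalence_logit(age, config):
    """Age-dependent offset on the liability logit (peak near 25y)."""
    age = np.asarray(age, dtype=float)
    return config.prev_base - ((age - config.prev_peak_age) / config.prev_width) ** 2


# --------------------------------------------------------------------------
# cohort

def generate_cohort(config):
    """One baseline scan per participant plus the ground-truth manifest."""
    rng_demo, rng_lat, rng_vol, *_ = _rngs(config)
    rows = []
    for s in config.studies:
        age = rng_demo.uniform(s.age_low, s.age_high, s.n)
        sex = (rng_demo.random(s.n) < s.sex_ratio).astype(int)
        hand = (rng_demo.random(s.n) < 0.1).astype(int)
        scanner = rng_demo.integers(0, s.n_scanners, s.n)
        for i in range(s.n):
            rows.append((f"{s.name}_{i:05d}", s.name,
                         f"{s.name}_sc{scanner[i]}", 1, age[i], sex[i], hand[i]))
    df = pd.DataFrame(rows, columns=["pid", "study", "scanner", "visit",
                                     "age", "sex", "hand"])
    n = len(df)

    # latent structure: shared component s links burden (b) and brain score (c)
    w = config.shared_frac
    u1 = rng_lat.standard_normal(n)
    u2 = rng_lat.standard_normal(n)
    sh = rng_lat.standard_normal(n)
    b = np.sqrt(1 - w) * u1 + np.sqrt(w) * sh
    c = np.sqrt(1 - w) * u2 + np.sqrt(w) * sh
    rho_f = config.factor_corr
    f_common = rng_lat.standard_normal(n)
    impulsivity = np.sqrt(1 - rho_f) * rng_lat.standard_normal(n) + \
        np.sqrt(rho_f) * f_common
    rule_breaking = np.sqrt(1 - rho_f) * rng_lat.standard_normal(n) + \
        np.sqrt(rho_f) * f_common

    logit = (config.w_genetic * b + config.w_impulsivity * impulsivity
             + prevalence_logit(df["age"], config))
    liability = 1.0 / (1.0 + np.exp(-logit))
    group = np.where(rng_lat.random(n) < liability, "SUD", "HC")
    df["group"] = group

    # per-study and per-scanner effects, drawn once from the config seed
    study_offsets = {
        s.name: (config.study_offset_sd * rng_vol.standard_normal()
                 if config.study_offset_sd > 0 else 0.0)
        for s in config.studies
    }
    batch_shift, batch_scale = {}, {}
    for s in config.studies:
        for k in range(s.n_scanners):
            key = f"{s.name}_sc{k}"
            batch_shift[key] = config.batch_shift_sd * rng_vol.standard_normal()
            batch_scale[key] = abs(1.0 + config.batch_scale_sd
                                   * rng_vol.standard_normal())

    age = df["age"].to_numpy()
    x = age / 10.0
    base_logmu = (config.beta_age[0] * x + config.beta_age[1] * x**2
                  + config.beta_sex * df["sex"].to_numpy()
                  + config.beta_hand * df["hand"].to_numpy()
                  + df["study"].map(study_offsets).to_numpy(float))
    sigma = np.exp(config.gamma0 + config.gamma_age[0] * x)
    is_sud = (group == "SUD").astype(float)

    roi_truth = {}
    true_logmu = {}
    normative_logmu = {}
    vols = {}
    brain_rois = [r.name for r in config.rois
                  if r.category == config.brain_coupled_category]
    theta = 1.0 / (sigma**2 * config.nu**2)
    scale = df["scanner"].map(batch_scale).to_numpy(float)
    shift_b = df["scanner"].map(batch_shift).to_numpy(float)
    for r in config.rois:
        shift = sud_offset(r.category, age, config) * sigma * is_sud
        if config.brain_effect_sd > 0 and r.name in brain_rois:
            shift = shift + config.brain_effect_sd * c * sigma
        logmu = np.log(r.base_volume) + base_logmu + shift
        g = rng_vol.gamma(shape=theta)
        y = np.exp(logmu) * (g / theta) ** (1.0 / config.nu)
        # scanner batch effect: residual rescaled, multiplicative shift; the
        # GG family is closed under this (mu *= e^shift, sigma *= scale,
        # nu /= scale), which the manifest records as the post-batch truth
        resid = np.log(y) - logmu
        vols[r.name] = np.exp(logmu + scale * resid + shift_b)
        true_logmu[r.name] = logmu + shift_b
        normative_logmu[r.name] = logmu - shift + shift_b
        roi_truth[r.name] = {
            "category": r.category,
            "base_volume": r.base_volume,
            "powers_mu": config.fp_powers_mu,
            "beta_age": config.beta_age,
            "brain_coupled": r.name in brain_rois and config.brain_effect_sd > 0,
        }
    for name, v in vols.items():
        df[name] = v

    # behavioral instrument scores from the latent factors
    factors = {"rule_breaking": rule_breaking
               + config.group_shift_rule_breaking * is_sud,
               "impulsivity": impulsivity}
    for inst, fac, lam in config.behavior_loadings:
        noise = rng_lat.standard_normal(n)
        df[inst] = lam * factors[fac] + np.sqrt(1 - lam**2) * noise

    participants = df[["pid", "study", "age", "sex", "hand", "group"]].copy()
    participants["u1"], participants["u2"], participants["shared"] = u1, u2, sh
    participants["burden"], participants["brain_score"] = b, c
    participants["impulsivity"] = impulsivity
    participants["rule_breaking"] = rule_breaking
    participants["liability"] = liability
    manifest = GroundTruthManifest(
        config=config,
        participants=participants,
        roi_truth=roi_truth,
        true_logmu=pd.DataFrame(true_logmu, index=df.index),
        normative_logmu=pd.DataFrame(normative_logmu, index=df.index),
        true_sigma=pd.Series(sigma * scale, index=df.index),
        true_nu=pd.Series(config.nu / scale, index=df.index),
    )
    return df, manifest


# --------------------------------------------------------------------------
# genotypes

def generate_genotypes(config, manifest=None):
    """LD-blocked dosages in {0,1,2} plus the variant map.

    Latent-Gaussian construction: two haplotype-level standard normal fields
    with AR(1) correlation inside blocks of ``block_len`` variants; alleles
    are the latents exceeding the MAF threshold.  Causal variants mix a
    fraction ``causal_tau`` of a participant latent (SUD-only: u1, brain-only:
    u2, shared: the shared component), which couples dosage to liability
    and/or to the brain score without changing the marginal MAF.
    """
    m, L = config.n_variants, config.block_len
    if m < 2 * L:
        raise ValueError("n_variants must be at least twice the block length")
    *_, rng_gen, _, _ = _rngs(config)
    if manifest is not None:
        part = manifest.participants
        n = len(part)
        targets = {
            "sud": part["u1"].to_numpy(),
            "brain": part["u2"].to_numpy(),
            "shared": part["shared"].to_numpy(),
        }
    else:
        n = 0
        targets = {}
    if n == 0:
        raise ValueError("genotypes require a cohort manifest")

    rho = config.block_rho
    maf = rng_gen.uniform(*config.maf_range, m)
    # deterministic causal placement: one causal variant per chosen block
    n_caus = config.n_causal_sud + config.n_causal_brain + config.n_causal_shared
    n_blocks = m // L
    if n_caus > n_blocks:
        raise ValueError("too many causal variants for the number of blocks")
    block_ids = np.linspace(0, n_blocks - 1, n_caus).astype(int) if n_caus else []
    causal = {}
    kinds = (["sud"] * config.n_causal_sud + ["brain"] * config.n_causal_brain
             + ["shared"] * config.n_causal_shared)
    for bi, kind in zip(block_ids, kinds):
        causal[bi * L] = kind      # first variant of the block

    tau = config.causal_tau
    G = np.empty((n, m), dtype=float)
    eps = rng_gen.standard_normal((2, n, m))
    e = np.empty((2, n))
    for j in range(m):
        if j % L == 0:
            e[:] = eps[:, :, j]
        else:
            e[:] = rho * e + np.sqrt(1 - rho**2) * eps[:, :, j]
        z = e
        if j in causal:
            t = targets[causal[j]]
            z = np.sqrt(1 - tau**2) * e + tau * t[None, :]
        thr = stats.norm.ppf(1.0 - maf[j])
        G[:, j] = (z[0] > thr).astype(float) + (z[1] > thr).astype(float)

    vm = pd.DataFrame({
        "chrom": "1",
        "pos": 10_000 + 2_000 * np.arange(m),
        "id": [f"snp_{j:05d}" for j in range(m)],
        "a1": "A",
        "a2": "G",
        "maf": maf,
    })
    causal_df = pd.DataFrame(
        [{"id": f"snp_{j:05d}", "index": j, "target": kind, "tau": tau}
         for j, kind in sorted(causal.items())]
    )
    if manifest is not None:
        manifest.causal_variants = causal_df
    return G, vm


# --------------------------------------------------------------------------
# atlas

def fibonacci_sphere(n):
    """Deterministic quasi-uniform unit-sphere placement (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = phi * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _geodesic_kernel(centroids, bandwidth):
    cosd = np.clip(centroids @ centroids.T, -1.0, 1.0)
    d = np.arccos(cosd)
    K = np.exp(-(d**2) / (2.0 * bandwidth**2))
    return K / K.sum(axis=1, keepdims=True)


def generate_atlas(config, manifest=None, bandwidth=None, noise_sd=None):
    """Term x parcel maps with smooth spatial factor structure.

    Term maps are ``loadings @ spatial factor patterns`` plus kernel-smoothed
    noise; patterns are geodesically smoothed standard-normal fields, so the
    maps carry realistic spatial autocorrelation.
    """
    if config.n_parcels < 24:
        raise ValueError("need at least 24 parcels")
    bandwidth = config.atlas_bandwidth if bandwidth is None else bandwidth
    noise_sd = config.atlas_noise_sd if noise_sd is None else noise_sd
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    *_, rng_atlas, _ = _rngs(config)
    P = fibonacci_sphere(config.n_parcels)
    K = _geodesic_kernel(P, bandwidth)
    k = config.n_atlas_factors
    patterns = K @ rng_atlas.standard_normal((config.n_parcels, k))
    # orthogonal smooth factor patterns: centre, orthogonalise, standardise
    patterns = patterns - patterns.mean(axis=0)
    patterns, _ = np.linalg.qr(patterns)
    patterns = patterns / patterns.std(axis=0)
    # block loading structure: each term loads mainly on one factor
    loadings = np.zeros((config.n_terms, k))
    for t in range(config.n_terms):
        f = t % k
        loadings[t, f] = 0.75 + 0.1 * rng_atlas.random()
        other = rng_atlas.integers(0, k)
        if other != f:
            loadings[t, other] = 0.1 * rng_atlas.random()
    noise = K @ rng_atlas.standard_normal((config.n_parcels, config.n_terms))
    terms = loadings @ patterns.T + noise_sd * noise.T
    term_df = pd.DataFrame(
        terms,
        index=[f"term_{t:03d}" for t in range(config.n_terms)],
        columns=[f"parcel_{p:03d}" for p in range(config.n_parcels)],
    )
    centroid_df = pd.DataFrame(P, columns=["x", "y", "z"],
                               index=term_df.columns)
    if manifest is not None:
        manifest.atlas_loadings = loadings
        manifest.atlas_patterns = patterns
    return term_df, centroid_df


# --------------------------------------------------------------------------
# follow-up

def generate_followup(scans, config, manifest=None):
    """Append revisit rows: age shifted by the interval, correlated volumes.

    Follow-up log-volumes track the participant's baseline deviation (high
    within-person correlation), move along the population age trend, and add
    ``slope_diff`` extra fractional decline per year for SUD rows.
    """
    df = pd.DataFrame(scans)
    probs = {name: (p, dt) for name, p, dt in config.followup_prob}
    for _, p, dt in config.followup_prob:
        if dt < 0:
            raise ValueError("follow-up interval must be non-negative")
    *_, rng_fu = _rngs(config)
    roi_cols = [r.name for r in config.rois if r.name in df.columns]
    x0 = df["age"].to_numpy() / 10.0
    rows = []
    logmu_rows = []
    sigma_rows = []
    revisit = np.zeros(len(df), dtype=bool)
    for name, (p, dt) in probs.items():
        mask = (df["study"] == name).to_numpy()
        revisit |= mask & (rng_fu.random(len(df)) < p)
    for i in np.where(revisit)[0]:
        row = df.iloc[i].copy()
        dt = probs[row["study"]][1]
        age1 = row["age"] + dt
        x1 = age1 / 10.0
        trend = (config.beta_age[0] * (x1 - x0[i])
                 + config.beta_age[1] * (x1**2 - x0[i] ** 2))
        extra = config.slope_diff * dt if row["group"] == "SUD" else 0.0
        new = row.copy()
        new["visit"] = int(row["visit"]) + 1
        new["age"] = age1
        for roi in roi_cols:
            noise = config.followup_within_sd * rng_fu.standard_normal()
            new[roi] = row[roi] * np.exp(trend + extra + noise)
        rows.append(new)
        if manifest is not None and manifest.true_logmu is not None:
            logmu_rows.append(manifest.true_logmu.iloc[i] + trend + extra)
            sigma_rows.append(manifest.true_sigma.iloc[i])
    if not rows:
        return df.copy()
    out = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# serialisation

def write_dataset(outdir, scans, manifest, genotypes=None, variant_map=None,
                  atlas_terms=None, centroids=None, vcf=False):
    """Write the TSV artefacts (scans, genotypes, atlas, manifest sidecar)."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scans.to_csv(out / "scans.tsv", sep="\t", index=False)
    manifest.participants.to_csv(out / "manifest.tsv", sep="\t", index=False)
    side = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(manifest.config).items()},
        "roi_truth": {k: {kk: (list(vv) if isinstance(vv, tuple) else vv)
                          for kk, vv in v.items()}
                      for k, v in manifest.roi_truth.items()},
    }
    if manifest.causal_variants is not None:
        side["causal_variants"] = manifest.causal_variants.to_dict("records")
    (out / "manifest.json").write_text(json.dumps(side, indent=1, default=str))
    if genotypes is not None:
        pd.DataFrame(genotypes).to_csv(out / "geno.tsv", sep="\t", index=False)
        variant_map.to_csv(out / "variants.tsv", sep="\t", index=False)
        if vcf:
            _write_vcf(out / "geno.vcf", genotypes, variant_map)
    if atlas_terms is not None:
        atlas_terms.to_csv(out / "atlas_terms.tsv", sep="\t")
        centroids.to_csv(out / "centroids.tsv", sep="\t")


def _write_vcf(path, genotypes, variant_map):
    G = np.asarray(genotypes)
    vm = pd.DataFrame(variant_map)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [f"s{i:05d}" for i in range(G.shape[0])]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in vm.iterrows():
            gts = "\t".join(gt_map.get(int(g), "./.") if np.isfinite(g) else "./."
                            for g in G[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['a2']}\t{row['a1']}\t.\tPASS\t.\tGT\t{gts}\n")
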