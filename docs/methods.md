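# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `sudtraj`.

## Generalized-gamma normative model

Healthy-control regional volumes are modeled with the Stacy generalized
gamma in the location–scale–shape convention: for response y > 0 with
location μ > 0, dispersion σ > 0 and power shape ν, let θ = 1/(σ²ν²) and
z = (y/μ)^ν; then θz ~ Gamma(θ, 1).  Useful special cases: σ = ν = 1 is
the exponential with mean μ; ν → 0 is the lognormal with log-median log μ
and log-SD σ.  The lognormal form is substituted whenever |ν| < 1e-4, where
the gamma-based expressions lose precision; the far tails use the
complementary regularized incomplete gamma (and its inverse) so centiles
stay monotone and invertible out to ~1e-300.

The regression structure is `log μ = FP(age)·β + sex + handedness
[+ study offsets]`, `log σ = FP(age)·γ`, ν constant.  FP bases follow the
Royston–Altman convention (powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
power 0 ↦ log x, a repeated power p ↦ x^p log x), with age rescaled to
decades so the columns are well conditioned over 8–70y.

**Model selection.** The BIC search runs over the FP degree of the location
basis (1..3), the FP degree of the dispersion basis (1..3), and
study-offset inclusion (when more than one study is present) — up to 18
likelihood fits.  Within a degree, the power multiset is chosen by a fast
least-squares screen: OLS of log-volume on each candidate basis for the
location (8/36/120 candidates at degrees 1/2/3), and OLS of the
log-squared-residual for the dispersion.  An exhaustive likelihood search
over all power multisets for both bases would need ~5·10⁴ optimisations per
region for no practical gain; in simulation the screen recovers the true
degree in ≥ 90% of replicates at n = 2000 and the screened-in power set
gives location curves within a few percent of truth across the age range.
The location and dispersion bases are searched independently: nothing
forces them to share powers, and the dispersion trend is usually much
simpler than the location trend.

**Optimisation.** L-BFGS-B on the unconstrained parameter vector (β, γ, ν),
warm-started from the log-scale OLS fits with ν = 0.5, function tolerance
1e-12, gradient tolerance 1e-8, up to three jittered restarts on failure.
The tight function tolerance matters: the likelihood is extremely flat in
ν when σ is small (the near-lognormal regime typical of brain volumes, with
relative dispersion ~9%), and a looser tolerance leaves ν at its starting
value.  ν is weakly identified in this regime — estimates at n = 2000 range
over roughly 0.5–1.7 around a true 0.8 — but centiles are insensitive to ν
precisely because the distribution is close to lognormal, and held-out
calibration is unaffected.

**Centiles.** Scans are scored as c = F(y; μ̂, σ̂, ν̂) with the z-equivalent
Φ⁻¹(c); centiles are clipped to [1e-7, 1−1e-7] before the probit so z stays
finite.  Scans outside the training age range are scored but flagged
`extrapolated`.  On held-out healthy data simulated from the true model at
n = 2000, mean centile is within 0.5 ± 0.02 and a Kolmogorov–Smirnov test
against Uniform(0,1) passes at p > 0.01 in most repetitions; because ~10
parameters are estimated from a same-sized training set, estimation noise
makes the KS test reject in roughly 5–10% of repetitions even when the
model family is exactly right — a property of the test at this sample size,
not a miscalibration.

**Study effects.** "Study-specific random effects" are implemented as study
fixed offsets on log μ competing in the BIC search.  A true mixed model
would shrink the offsets but adds substantial fitting cost; with a handful
of studies the fixed-offset BIC comparison preserves the inclusion test.
This is a documented simplification.

## Scanner harmonization

Parametric empirical-Bayes location/scale (ComBat) adjustment: each feature
is standardized on a covariate fit, per-batch means and variances are
shrunk toward priors pooled across features (normal prior for locations,
inverse-gamma moment-matched prior for scales, iterated to convergence),
the shrunken effects are removed and the data transformed back.  A single
batch is returned unchanged; a zero-variance batch falls back to mean-only
adjustment with a warning.  `shrink=False` removes the raw per-batch
location/scale exactly; that mode is idempotent to machine precision,
whereas EB shrinkage intentionally leaves sampling-noise-sized per-feature
residuals (the cost of borrowing strength), so a second EB pass changes
values at the 1e-3 relative level.  Per-batch variances use the same n
denominator as the pooled variance so that the exact mode leaves unit
within-batch variance.

## Trajectory divergence

Volumes are first adjusted for sex, handedness and study by a pooled linear
model (the covariate effects are assumed identical in both groups);
residuals keep the grand mean.  Each group's trajectory is an OLS natural
cubic spline of adjusted volume on age with K = 3 interior knots.  The
stated knot rule places them at age "terciles"; three knots need three cut
points, so the package uses the 25/50/75% age quantiles of the fitted group
(K is configurable).  Pointwise standard errors are
se(a) = √(x(a)ᵀ V x(a)) with V the OLS coefficient covariance; natural
splines are linear beyond the boundary knots, and grid ages outside a
group's observed range are flagged and excluded from window calling.

On the 1241-point grid (8.00–70.00, step 0.05), z(a) =
(m_SUD − m_HC)/√(se²_SUD + se²_HC), two-sided normal p, BH step-up FDR
across the grid within each region, and maximal runs of q < 0.05 reported
as closed windows at grid resolution (edges are not interpolated).  Under
the global null the family-wise any-window rate is ~3–4% at n = 1000/group
(BH over strongly correlated smooth tests is conservative).  With a
0.5-SD offset injected at ages 40–50 and n = 3000/group, windows
intersecting the true span are found in ~95–100% of replicates; because a
3-knot spline cannot represent a box-shaped offset locally, the detection
window smears to ~20–26y and small spurious ripple windows occasionally
appear elsewhere, so total significant coverage is typically ~23y (about a
third of the span) with occasional excursions past half.

The "continuous significance trajectory" is a cubic-spline smoother of the
signed curve sign(z)·(−log₁₀ q); its crossings of the 0.05 level are
reported as window edges.  The smoother is an interpretation — the raw
windows are the primary output.

Validation machinery: per-participant annualized volume change regressed on
group, baseline age and sex; inverse-variance pooling (weights se⁻², pooled
SE (Σw)^{−1/2}); Spearman correlation of discovery and validation z-curves
over their overlapping ages (undefined below 3 shared grid points);
agglomerative average-linkage clustering of regions on correlation distance
of centile patterns, constant regions dropped with a warning.  Substance
subgroup reruns (alcohol/tobacco/marijuana/other) are plain relabelings of
the group column through the identical code path.

## Behavioral analysis

Group comparisons use the linear model score ~ group + covariates; Cohen's
d is the adjusted group coefficient over the residual SD, with BH-FDR
within study.  With heavy class imbalance the majority controls can be
down-sampled 1:1 with the cases; the default is 1000 repeats with median
aggregation (the repeat scheme is the package's choice).  The age-by-group
interaction model is score ~ age + group + age·group (+ sex + hand) with a
condition-number guard.

Common factors use principal-axis extraction on the (pairwise-complete)
instrument correlation matrix with squared-multiple-correlation starting
communalities, retention by the strict Kaiser rule (eigenvalues > 1),
varimax rotation, and Thompson regression scores rescaled to unit variance.
Sign convention: the instrument with the largest absolute loading loads
positively, which makes scores bit-for-bit reproducible.  Factors are
labeled by that instrument (optionally mapped to "rule_breaking" /
"impulsivity").  Brain–behavior associations are Pearson correlations
between factor scores and regional centiles, partial correlations when
conditioning on the other factor, BH-FDR across regions; adolescent-study
effect sizes are pooled on the Fisher-z scale with weights n − 3 (studies
with n ≤ 3 are excluded).

## Atlas factor maps and spin permutation

The term × parcel matrix is factor-analyzed with parcels as observations;
factors explaining > 1% of total variance are retained, and each factor
keeps only terms whose absolute loading exceeds 0.2 AND reaches the
factor's median absolute loading (absolute loadings are used; the signed
alternative is not).  Factor maps are per-factor regression scores computed
from the retained terms only — the full term correlation matrix is
rank-deficient whenever parcels are fewer than terms, so each factor's
weights are solved on its own retained submatrix.

Spin inference: observed R² from the univariate regression of the
differential z map on the factor map; the null rotates the parcel centroids
by uniform random rotations (QR of Gaussian 3×3 matrices, determinant fixed
to +1) and reassigns each parcel the factor value of its nearest rotated
centroid (duplicates allowed, the standard spin behavior); one-sided
p = (1 + #{null ≥ observed})/(1 + n_spins).  Parcels without spherical
coordinates (subcortex) are value-permuted instead and flagged.  Age
profiles evaluate every factor at 0.5y steps (125 ages) with BH-FDR across
ages within factor and a peak-age summary.  On smooth synthetic maps the
spin null preserves spatial autocorrelation and rejects a true-null
association less often than a naive label shuffle, as intended; on
independent maps the rejection rate is calibrated at ~5%.

## Genetics

QC thresholds: sample missingness > 10%, variant call rate < 95%,
MAF < 1%, Hardy–Weinberg chi-square (1 df on genotype counts) p < 1e-10.
Longitudinal case collapsing: case iff strictly more than half of a
participant's visits are labeled SUD (the boundary visit pattern SUD/HC is
a control).  Association is covariate-adjusted Wald: a batched Newton
solver for logistic regression (one Hessian solve per variant per
iteration, warm-started from the covariate-only fit; agrees with
statsmodels to 1e-6) and closed-form Frisch–Waugh OLS for continuous
phenotypes.  Mixed-model/saddlepoint machinery is not implemented: at
synthetic scale and moderate imbalance the plain Wald test is calibrated
(null |z| > 1.96 rate 5% ± 1% at 5000 variants), but with extreme
case-control imbalance it would inflate — a known caveat.

The wGMV score is Σ_r w_r·centile_r; the default weight vector is the
regional SUD–HC differential z (at a reference age such as the study mean),
with a GWAS-derived z vector accepted as the alternative weighting.
LD pruning is greedy indep-pairwise: within each 50kb window any pair with
dosage r² > 0.1 loses the lower-MAF member (tie: the later position), the
window slides by 5 variants, and an exhaustive post-check confirms no
retained within-window pair exceeds the threshold.  PGS = Σ dosage·β over
the pruned set with per-variant mean imputation and allele alignment
(swapped alleles reverse the dosage; other mismatches are dropped and
counted).  PGS-based genetic correlation reports the standardized slope,
incremental R² and p from the covariate-adjusted regression, flagged
`uncorrected` (no attenuation correction is applied).

Conditional FDR uses the pointwise empirical estimator
cFDR(p₁|p₂) = p₁·#{P₂ ≤ p₂}/#{P₁ ≤ p₁ ∧ P₂ ≤ p₂}, evaluated at each
variant's own pair and capped at 1 (no kernel smoothing or binning);
conjFDR is the elementwise maximum, and significant variants are clumped to
one lead per LD neighborhood (best conjFDR first).  The estimator is
checked exactly against a brute-force counting oracle.

## Synthetic-data generator

The generator's defaults are the study conditions for every simulation-based
test.  Four studies emulate the pooled design — adolescent (9–11.5y,
n=900, 3 scanners), youth (14–23.5y, n=500, 4 scanners), young-adult
(22–37y, n=500, 1 scanner) and aging (45–70y, n=1100, 3 scanners) — giving
the age-window gaps and scanner structure of real multi-cohort pooling at
desk scale (n=3000).  Regional volumes follow the generalized gamma with
log μ quadratic in age/10 (peak ~25y, ~24% decline to 70y), σ ≈ 9% rising
slowly with age, ν = 0.8, a 4% male offset, and per-scanner multiplicative
shift (SD 0.02 log units) and residual scale (SD 0.05).  The scanner
transform is a shift/power map under which the generalized gamma family is
closed, so the manifest records exact post-batch (μ, σ, ν) per scan and
true centiles are Uniform(0,1) by construction.

SUD–HC offsets come in three temporal classes, in within-person SD units:
early = −0.35·exp(−(age−8)/5) (gone by ~25y), mid = +0.35·Gaussian bump
centered at 45y with width 12y (the salience-network-like positive offset
emerging ~30y and fading after 60y), late = −0.45·logistic rising after
45y.  No effect-size magnitudes are published for these classes; the
amplitudes are plausible defaults exposed in the config, chosen once so the
designed signals are detectable at desk-scale n, and are not claims about
real effect sizes.

SUD liability is logistic(0.8·genetic burden + 0.5·impulsivity + age
offset), the age offset a downward parabola in age peaking at 25y
(prevalence ~17% overall under the defaults).  Because liability depends on
age while volumes also depend on age, raw SUD–HC volume contrasts are
confounded by the age-dependent selection — exactly as in real cohorts —
so null-case checks use a flat-prevalence configuration.

Genotypes use latent-Gaussian thresholding: two haplotype-level standard
normal fields with AR(1) correlation (ρ = 0.45) inside blocks of 5
variants; an allele is the latent exceeding the MAF threshold (MAF uniform
on 0.10–0.45).  Causal variants mix a fraction τ = 0.35 of a participant
latent into their haplotype field — SUD-only variants couple to the
burden-specific component, brain-only variants to the brain-specific
component, shared variants to the common component (overlap fraction 0.5) —
which induces dosage–trait correlation without changing marginal MAF.
Brain-coupled regions (the mid-life class by default) shift their log-volume
by κ·(brain score)·σ when κ > 0.  This latent-factor construction is the
simplest structure that gives tunable LD plus a genuinely shared
architecture linking the wGMV → GWAS → conjFDR chain.  Follow-up visits
advance age by a per-study interval, carry the participant's deviation
(within-person correlation > 0.9), and add a configured extra fractional
decline per year for SUD (−0.5%/yr default).  Atlas maps place parcels on a
Fibonacci sphere lattice; spatial factor patterns are geodesically smoothed
Gaussian fields, centered, orthogonalized and standardized; term maps are
block loadings times patterns plus smoothed noise.

What the generator does **not** emulate: real covariance between regions
beyond the shared age trend and latent factors, site-by-age interactions,
non-gamma measurement artifacts, genotype ascertainment, linkage across
blocks, or questionnaire item structure.  Passing tests therefore
demonstrate correctness of the machinery under the stated generative model,
not robustness to every real-data pathology.

## Numerical and design choices

- Centile clipping [1e-7, 1−1e-7] before the probit; GG tails via the
  complementary incomplete gamma for negative ν.
- BH-FDR is delegated to statsmodels' step-up implementation; the test
  suite checks it exactly against an independent brute-force oracle, as it
  does for the conditional FDR and the pruning post-condition.
- Pruning tie-breaks (drop lower MAF, then later position) are fixed purely
  for determinism.
- Spin rotations come from QR-orthogonalized Gaussian matrices with the
  sign convention that makes the decomposition unique and det = +1.
- Empty age bins in one-visit sampling fall back to uniform weights with a
  warning; rank-deficient covariate designs drop aliased columns with a
  warning.
- Problem sizes in the test-suite simulations (n ≈ 1000–3000 per group,
  20–200 replicates, 100–1000 spins, 120–5000 variants) were chosen as the
  smallest sizes at which the calibration and recovery properties are
  stable.

## Known limitations

- Study effects are fixed offsets, not random effects; with many small
  studies the BIC inclusion test would behave differently.
- ν is weakly identified in the near-lognormal regime; its point estimate
  should not be interpreted, only the implied centiles.
- The divergence spline cannot localize sharp offsets; window edges are
  biased outward by smoothing, and remote low-amplitude ripple windows can
  appear at large n.
- Logistic Wald association is anti-conservative under extreme case-control
  imbalance or separation (separated variants are flagged missing).
- The PGS-based genetic-correlation estimate is uncorrected for PGS
  measurement error and is flagged as such.
- Spin nulls require spherical coordinates; subcortical parcels fall back
  to value permutation, which does not preserve spatial autocorrelation.
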