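"""Genotype QC, association, wGMV, pruning, PGS and cond/conjFDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sudtraj.genetics import (
    collapse_case_control,
    compute_wgmv,
    cond_fdr,
    conj_fdr,
    gene_pgs_compare,
    ld_prune,
    pgs_genetic_correlation,
    pgs_score,
    qc_filter,
    snp_association,
)


def brute_force_cond_fdr(p1, p2):
    """Independent counting oracle for the pointwise empirical cFDR."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    out = []
    for a, b in zip(p1, p2):
        n_cond = sum(1 for x in p2 if x <= b)
        n_both = sum(1 for x, y in zip(p1, p2) if x <= a and y <= b)
        out.append(1.0 if n_both == 0 else min(1.0, a * n_cond / n_both))
    return np.array(out)


def _variant_map(m, spacing=2000):
    return pd.DataFrame({
        "chrom": "1", "pos": 10_000 + spacing * np.arange(m),
        "id": [f"v{j}" for j in range(m)], "a1": "A", "a2": "G",
    })


# -- QC ---------------------------------------------------------------------

def test_hwe_conforming_variant_retained(rng):
    G = rng.binomial(2, 0.3, (5000, 1)).astype(float)
    _, vm, _, report = qc_filter(G, _variant_map(1))
    assert report["n_variants_kept"] == 1


def test_zero_heterozygote_variant_dropped(rng):
    # MAF 0.3 but no heterozygotes: HWE chi-square p << 1e-10
    g = np.r_[np.zeros(3500), np.full(1500, 2.0)]
    rng.shuffle(g)
    good = rng.binomial(2, 0.3, 5000).astype(float)
    G = np.c_[g, good]
    _, vm, _, report = qc_filter(G, _variant_map(2))
    assert report["dropped_hwe"] == 1 and list(vm["id"]) == ["v1"]


def test_high_missingness_sample_dropped(rng):
    G = rng.binomial(2, 0.3, (50, 20)).astype(float)
    G[0, :3] = np.nan  # 15% missing
    _, _, keep, report = qc_filter(G, _variant_map(20))
    assert not keep[0] and report["n_samples_dropped"] == 1


def test_low_maf_and_call_rate_dropped(rng):
    n = 2000
    rare = rng.binomial(2, 0.003, n).astype(float)
    patchy = rng.binomial(2, 0.3, n).astype(float)
    patchy[: int(0.1 * n)] = np.nan
    good = rng.binomial(2, 0.3, (n, 40)).astype(float)
    G = np.c_[rare, patchy, good]   # per-sample missingness stays < 10%
    _, vm, keep, report = qc_filter(G, _variant_map(42))
    assert keep.all()
    assert report["dropped_maf"] >= 1 and report["dropped_call_rate"] == 1
    assert "v0" not in list(vm["id"]) and "v1" not in list(vm["id"])


# -- case/control collapsing ------------------------------------------------

@pytest.mark.parametrize(
    "labels,expected",
    [
        (["SUD", "SUD", "HC"], 1),   # 2 > 1.5
        (["HC", "HC"], 0),
        (["SUD", "HC"], 0),          # 1 is not > 1
        (["SUD"], 1),
    ],
)
def test_collapse_case_control(labels, expected):
    df = pd.DataFrame({"pid": "p", "group": labels})
    assert collapse_case_control(df).loc["p"] == expected


# -- association ------------------------------------------------------------

def test_linear_association_matches_statsmodels(rng):
    import statsmodels.api as sm

    n = 300
    G = rng.binomial(2, 0.3, (n, 4)).astype(float)
    C = rng.standard_normal((n, 2))
    y = rng.standard_normal(n) + 0.2 * G[:, 0]
    tab = snp_association(G, y, C)
    for j in range(4):
        X = sm.add_constant(np.c_[C, G[:, j]])
        fit = sm.OLS(y, X).fit()
        assert tab.beta[j] == pytest.approx(fit.params[-1], rel=1e-8)
        assert tab.se[j] == pytest.approx(fit.bse[-1], rel=1e-8)


def test_logistic_association_matches_statsmodels(rng):
    import statsmodels.api as sm

    n = 500
    G = rng.binomial(2, 0.3, (n, 3)).astype(float)
    C = rng.standard_normal((n, 1))
    yb = rng.binomial(1, 0.4, n).astype(float)
    tab = snp_association(G, yb, C)
    for j in range(3):
        X = sm.add_constant(np.c_[C, G[:, j]])
        fit = sm.Logit(yb, X).fit(disp=0)
        assert tab.beta[j] == pytest.approx(fit.params[-1], abs=1e-6)
        assert tab.se[j] == pytest.approx(fit.bse[-1], abs=1e-6)


def test_constant_variant_flagged_missing(rng):
    n = 200
    G = np.c_[np.full(n, 1.0), rng.binomial(2, 0.3, n).astype(float)]
    tab = snp_association(G, rng.standard_normal(n))
    assert np.isnan(tab.beta[0]) and np.isfinite(tab.beta[1])


def test_effect_recovery_with_ci_coverage(rng):
    cover = 0
    reps = 60
    for _ in range(reps):
        n = 400
        g = rng.binomial(2, 0.3, (n, 1)).astype(float)
        y = 0.3 * g[:, 0] + rng.standard_normal(n)
        tab = snp_association(g, y)
        lo = tab.beta[0] - 1.96 * tab.se[0]
        hi = tab.beta[0] + 1.96 * tab.se[0]
        cover += lo <= 0.3 <= hi
    assert cover / reps > 0.85


# -- wGMV -------------------------------------------------------------------

def test_wgmv_zero_weights():
    cent = pd.DataFrame({"a": [0.5, 0.2], "b": [0.7, 0.9]}, index=["p1", "p2"])
    score = compute_wgmv(cent, {"a": 0.0, "b": 0.0})
    assert (score == 0).all()


def test_wgmv_one_hot_and_arithmetic():
    cent = pd.DataFrame({"a": [0.2], "b": [0.8]}, index=["p1"])
    assert compute_wgmv(cent, {"a": 1.0, "b": 0.0}).loc["p1"] == 0.2
    assert compute_wgmv(cent, {"a": 1.0, "b": -1.0}).loc["p1"] == \
        pytest.approx(-0.6)


def test_wgmv_missing_centile_skips_with_warning():
    cent = pd.DataFrame({"a": [0.2, np.nan], "b": [0.8, 0.5]},
                        index=["p1", "p2"])
    with pytest.warns(UserWarning, match="skipped"):
        score = compute_wgmv(cent, {"a": 1.0, "b": 1.0})
    assert list(score.index) == ["p1"]


def test_wgmv_requires_weight_coverage():
    cent = pd.DataFrame({"a": [0.2]}, index=["p1"])
    with pytest.raises(ValueError):
        compute_wgmv(cent, {"a": 1.0, "zzz": 1.0})


# -- LD pruning -------------------------------------------------------------

def test_duplicate_variants_pruned_to_one(rng):
    g = rng.binomial(2, 0.3, (500, 1)).astype(float)
    G = np.c_[g, g]
    vm = _variant_map(2, spacing=1000)
    keep = ld_prune(G, vm)
    assert len(keep) == 1


def test_independent_variants_all_retained(rng):
    G = rng.binomial(2, 0.3, (2000, 20)).astype(float)
    keep = ld_prune(G, _variant_map(20))
    assert len(keep) == 20


def test_chain_pruning_leaves_no_correlated_pair(rng):
    # A-B-C chain with r2(A,B) = r2(B,C) ~ 0.5, r2(A,C) ~ 0
    n = 4000
    a = rng.standard_normal(n)
    c = rng.standard_normal(n)
    b = np.sqrt(0.5) * a + np.sqrt(0.5) * c
    thr = 0.0

    def dose(x):
        return (x > thr).astype(float) + (x + rng.standard_normal(n) * 0.05 > thr)

    G = np.c_[dose(a), dose(b), dose(c)]
    vm = _variant_map(3, spacing=1000)
    keep = ld_prune(G, vm)
    # exhaustive post-check over retained pairs
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            r = np.corrcoef(G[:, keep[i]], G[:, keep[j]])[0, 1]
            assert r * r <= 0.1


def test_prune_postcondition_on_ld_blocks():
    from sudtraj.simulate import SimConfig, StudySpec, generate_cohort, \
        generate_genotypes

    cfg = SimConfig(seed=13, n_variants=120, block_len=4, block_rho=0.8,
                    studies=(StudySpec("u", 8, 70, 800, 0.5, 1),))
    _, man = generate_cohort(cfg)
    G, vm = generate_genotypes(cfg, man)
    keep = ld_prune(G, vm)
    assert 0 < len(keep) < 120
    pos = vm["pos"].to_numpy()
    for x in range(len(keep)):
        for y in range(x + 1, len(keep)):
            i, j = keep[x], keep[y]
            if abs(pos[i] - pos[j]) <= 50_000:
                r = np.corrcoef(G[:, i], G[:, j])[0, 1]
                assert r * r <= 0.1 + 1e-12


def test_unsorted_positions_rejected(rng):
    G = rng.binomial(2, 0.3, (100, 2)).astype(float)
    vm = _variant_map(2)
    vm.loc[0, "pos"], vm.loc[1, "pos"] = vm.loc[1, "pos"], vm.loc[0, "pos"]
    with pytest.raises(ValueError):
        ld_prune(G, vm)


# -- PGS --------------------------------------------------------------------

def test_pgs_zero_betas(rng):
    G = rng.binomial(2, 0.3, (50, 5)).astype(float)
    vm = _variant_map(5)
    gt = vm.assign(beta=0.0)
    score, dropped = pgs_score(G, gt, vm)
    assert (score == 0).all() and dropped == 0


def test_pgs_single_variant_equals_dosage(rng):
    G = rng.binomial(2, 0.3, (50, 1)).astype(float)
    vm = _variant_map(1)
    score, _ = pgs_score(G, vm.assign(beta=1.0), vm)
    assert np.allclose(score, G[:, 0])


def test_pgs_allele_swap_reverses_dosage(rng):
    G = rng.binomial(2, 0.3, (50, 1)).astype(float)
    vm = _variant_map(1)
    gt = vm.assign(beta=1.0)
    gt.loc[0, ["a1", "a2"]] = ["G", "A"]
    score, dropped = pgs_score(G, gt, vm)
    assert np.allclose(score, 2.0 - G[:, 0]) and dropped == 0


def test_pgs_mismatched_alleles_dropped(rng):
    G = rng.binomial(2, 0.3, (50, 1)).astype(float)
    vm = _variant_map(1)
    gt = vm.assign(beta=1.0)
    gt.loc[0, ["a1", "a2"]] = ["T", "C"]
    score, dropped = pgs_score(G, gt, vm)
    assert dropped == 1 and (score == 0).all()


def test_pgs_from_true_betas_tracks_liability():
    from sudtraj.simulate import SimConfig, StudySpec, generate_cohort, \
        generate_genotypes

    cfg = SimConfig(seed=17, prev_width=1e6, causal_tau=0.5,
                    studies=(StudySpec("u", 8, 70, 2000, 0.5, 1),))
    scans, man = generate_cohort(cfg)
    G, vm = generate_genotypes(cfg, man)
    y = (scans.group == "SUD").astype(float).to_numpy()
    tab = snp_association(G, y, variant_map=vm)
    keep = ld_prune(G, vm)
    score, _ = pgs_score(G, tab, vm, pruned_idx=keep)
    burden = man.participants["burden"].to_numpy()
    assert np.corrcoef(score, burden)[0, 1] > 0.3


# -- PGS genetic correlation ------------------------------------------------

def test_pgs_correlation_null(rng):
    pgs = rng.standard_normal(500)
    target = rng.standard_normal(500)
    res = pgs_genetic_correlation(pgs, target)
    assert res["p"] > 0.001 and res["uncorrected"] is True


def test_pgs_correlation_r2_invariant_to_rescaling(rng):
    pgs = rng.standard_normal(500)
    target = pgs + rng.standard_normal(500)
    r1 = pgs_genetic_correlation(pgs, target)
    r2 = pgs_genetic_correlation(10.0 * pgs + 3.0, target)
    assert r1["r2"] == pytest.approx(r2["r2"], rel=1e-9)


def test_pgs_correlation_errors(rng):
    with pytest.raises(ValueError):
        pgs_genetic_correlation(rng.standard_normal(50), rng.standard_normal(50))
    with pytest.raises(ValueError):
        pgs_genetic_correlation(np.ones(200), rng.standard_normal(200))


# -- conditional / conjunctional FDR ---------------------------------------

def test_cond_fdr_uninformative_conditioning_worked_example():
    p1 = np.arange(1, 11) / 100.0   # 0.01 .. 0.10
    p2 = np.ones(10)
    c = cond_fdr(p1, p2)
    assert c[0] == pytest.approx(0.01 * 10 / 1)   # = 0.10


def test_cond_fdr_dominates_p1(rng):
    p1, p2 = rng.random(300), rng.random(300)
    c = cond_fdr(p1, p2)
    assert np.all(c >= p1 - 1e-12)


def test_cond_fdr_matches_brute_force(rng):
    for n in (10, 87, 500):
        p1, p2 = rng.random(n), rng.random(n)
        assert np.allclose(cond_fdr(p1, p2), brute_force_cond_fdr(p1, p2),
                           atol=1e-14)
    # perfect pleiotropy: p1 == p2
    p = rng.random(200)
    assert np.allclose(cond_fdr(p, p), brute_force_cond_fdr(p, p), atol=1e-14)


def test_conj_fdr_elementwise_max():
    conj, leads = conj_fdr([0.01, 0.2], [0.03, 0.1])
    assert np.allclose(conj, [0.03, 0.2])
    assert leads == [0]
    c1, c2 = np.array([0.01, 0.5]), np.array([0.4, 0.02])
    conj, _ = conj_fdr(c1, c2)
    assert np.all(conj >= c1) and np.all(conj >= c2)


def test_conj_fdr_clumps_ld_neighbors(rng):
    g = rng.binomial(2, 0.3, (500, 1)).astype(float)
    G = np.c_[g, g, rng.binomial(2, 0.3, 500).astype(float)]
    vm = _variant_map(3, spacing=1000)
    conj, leads = conj_fdr([0.01, 0.02, 0.03], [0.01, 0.02, 0.03],
                           variant_map=vm, dosages=G)
    assert leads == [0, 2]   # duplicate absorbed, independent variant kept


# -- gene-level PGS comparison ---------------------------------------------

def test_gene_pgs_compare_null_and_sign(rng):
    pgs = rng.standard_normal(400)
    groups = np.where(rng.random(400) < 0.5, "SUD", "HC")
    d, p = gene_pgs_compare(pgs, groups)
    assert abs(d) < 0.3
    pgs2 = pgs + 0.5 * (groups == "SUD")
    d1, _ = gene_pgs_compare(pgs2, groups)
    flipped = np.where(groups == "SUD", "HC", "SUD")
    d2, _ = gene_pgs_compare(pgs2, flipped)
    assert d1 == pytest.approx(-d2)
    assert d1 > 0


def test_gene_pgs_compare_small_groups_refused(rng):
    with pytest.raises(ValueError):
        gene_pgs_compare(rng.standard_normal(12),
                         ["SUD"] * 5 + ["HC"] * 7)


def test_wgmv_weights_from_divergence_grids(rng):
    from sudtraj.divergence import divergence_grid, fit_group_trajectory
    from sudtraj.genetics import wgmv_weights

    a1, a2 = rng.uniform(8, 70, 300), rng.uniform(8, 70, 300)
    grids = {}
    for roi, shift in (("a", 1.0), ("b", 0.0)):
        grids[roi] = divergence_grid(
            fit_group_trajectory(rng.normal(size=300) + shift, a1),
            fit_group_trajectory(rng.normal(size=300), a2), roi=roi)
    w = wgmv_weights(grids, 40.0)
    assert w["a"] == grids["a"].z_at(40.0)
    assert abs(w["a"]) > abs(w["b"])
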