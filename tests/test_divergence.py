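"""Trajectory fitting, grid divergence, FDR, meta-analysis, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sudtraj.divergence import (
    AGE_GRID,
    adjust_covariates,
    bh_fdr,
    cluster_centile_patterns,
    consistency_correlation,
    divergence_grid,
    fit_group_trajectory,
    ivw_meta,
    longitudinal_change_rate,
    significance_trajectory,
)
from sudtraj.simulate import SimConfig, StudySpec, generate_cohort, generate_followup
from sudtraj.splines import NaturalSplineTrajectory


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


# -- covariate adjustment ---------------------------------------------------

def test_zero_covariate_effects_leave_values(rng):
    y = rng.normal(size=500)
    cov = {"sex": rng.integers(0, 2, 500), "hand": rng.integers(0, 2, 500)}
    adj = adjust_covariates(y, cov)
    assert np.corrcoef(adj, y)[0, 1] > 0.99


def test_planted_sex_effect_removed(rng):
    sex = rng.integers(0, 2, 2000)
    y = rng.normal(1000, 30, 2000) + 100.0 * sex
    adj = adjust_covariates(y, {"sex": sex})
    diff = adj[sex == 1].mean() - adj[sex == 0].mean()
    assert abs(diff) < 5.0


def test_location_equivariance(rng):
    sex = rng.integers(0, 2, 300)
    y = rng.normal(size=300)
    a1 = adjust_covariates(y, {"sex": sex})
    a2 = adjust_covariates(y + 7.0, {"sex": sex})
    assert np.allclose(a2, a1 + 7.0, atol=1e-9)


def test_rank_deficient_design_warns(rng):
    sex = rng.integers(0, 2, 100)
    with pytest.warns(UserWarning, match="rank-deficient"):
        adjust_covariates(rng.normal(size=100), {"a": sex, "b": sex})


# -- spline trajectories ----------------------------------------------------

def test_spline_reproduces_straight_line():
    age = np.linspace(8, 70, 200)
    y = 3.0 + 0.5 * age
    traj = fit_group_trajectory(y, age)
    grid = np.linspace(8, 70, 50)
    assert np.max(np.abs(traj.predict(grid) - (3.0 + 0.5 * grid))) < 1e-6


def test_duplicated_data_halves_variance(rng):
    age = rng.uniform(8, 70, 400)
    y = rng.normal(size=400)
    t1 = fit_group_trajectory(y, age)
    t2 = fit_group_trajectory(np.r_[y, y], np.r_[age, age])
    ratio = t2.predict_se([30.0, 50.0]) / t1.predict_se([30.0, 50.0])
    assert np.allclose(ratio, 1 / np.sqrt(2), atol=0.04)


def test_quadratic_truth_recovered(rng):
    age = rng.uniform(8, 70, 2000)
    y = 0.01 * (age - 40) ** 2 + rng.normal(0, 1, 2000)
    traj = fit_group_trajectory(y, age)
    grid = np.linspace(10, 68, 30)
    err = np.abs(traj.predict(grid) - 0.01 * (grid - 40) ** 2)
    assert err.max() < 0.25


def test_identical_ages_rejected():
    with pytest.raises(ValueError):
        fit_group_trajectory(np.ones(50), np.full(50, 30.0))


def test_grid_z_matches_independent_ols_prediction(rng):
    """Oracle: statsmodels OLS mean-prediction SEs on the same basis."""
    import statsmodels.api as sm

    from sudtraj.splines import natural_spline_basis

    age1, age2 = rng.uniform(8, 70, 500), rng.uniform(8, 70, 500)
    y1 = rng.normal(size=500) + 0.01 * age1
    y2 = rng.normal(size=500)
    t1, t2 = fit_group_trajectory(y1, age1), fit_group_trajectory(y2, age2)
    grid = divergence_grid(t1, t2)
    sub = np.linspace(9, 69, 20)

    def ols_pred(traj, age, y, at):
        X = natural_spline_basis(age, traj.knots_, traj.boundary_)
        fit = sm.OLS(y, X).fit()
        pred = fit.get_prediction(
            natural_spline_basis(at, traj.knots_, traj.boundary_))
        return pred.predicted_mean, pred.se_mean

    idx = [int(np.argmin(np.abs(grid.ages - a))) for a in sub]
    at = grid.ages[idx]
    m1, s1 = ols_pred(t1, age1, y1, at)
    m2, s2 = ols_pred(t2, age2, y2, at)
    z_ref = (m1 - m2) / np.sqrt(s1**2 + s2**2)
    assert np.max(np.abs(grid.z[idx] - z_ref)) < 1e-10


# -- divergence grid --------------------------------------------------------

def test_identical_groups_give_zero_z(rng):
    age = rng.uniform(8, 70, 300)
    y = rng.normal(size=300)
    t = fit_group_trajectory(y, age)
    grid = divergence_grid(t, t)
    assert np.allclose(grid.z, 0.0)
    assert grid.windows == []


def test_group_swap_negates_z(rng):
    a1, a2 = rng.uniform(8, 70, 300), rng.uniform(8, 70, 300)
    t1 = fit_group_trajectory(rng.normal(size=300) + 1, a1)
    t2 = fit_group_trajectory(rng.normal(size=300), a2)
    g12 = divergence_grid(t1, t2)
    g21 = divergence_grid(t2, t1)
    assert np.allclose(g12.z, -g21.z)
    assert np.allclose(g12.q, g21.q)


def test_grid_shape_and_frame():
    assert len(AGE_GRID) == 1241
    assert AGE_GRID[0] == 8.0 and AGE_GRID[-1] == 70.0
    rng = np.random.default_rng(1)
    t = fit_group_trajectory(rng.normal(size=100), rng.uniform(8, 70, 100))
    g = divergence_grid(t, t)
    df = g.to_frame()
    assert list(df.columns)[:2] == ["roi", "age"] and len(df) == 1241


def test_missing_trajectory_rejected(rng):
    t = fit_group_trajectory(rng.normal(size=100), rng.uniform(8, 70, 100))
    with pytest.raises(ValueError):
        divergence_grid(t, None)


def test_subgroup_relabel_reuses_pipeline(rng):
    """Relabelled group column coinciding with the original labels must give
    the identical divergence result (subgroup reruns share the code path)."""
    age_s, age_h = rng.uniform(8, 70, 400), rng.uniform(8, 70, 400)
    y_s, y_h = rng.normal(size=400) + 0.3, rng.normal(size=400)
    g1 = divergence_grid(fit_group_trajectory(y_s, age_s),
                         fit_group_trajectory(y_h, age_h))
    # relabel: 'alcohol' subgroup equals the full SUD set
    g2 = divergence_grid(fit_group_trajectory(y_s, age_s),
                         fit_group_trajectory(y_h, age_h), roi="alcohol")
    assert np.array_equal(g1.z, g2.z) and g1.windows == g2.windows


# -- BH-FDR -----------------------------------------------------------------

def test_bh_worked_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_edge_cases():
    assert bh_fdr([0.37]) == pytest.approx([0.37])
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    assert bh_fdr([]).size == 0


def test_bh_matches_brute_force_oracle(rng):
    for n in (1, 7, 100, 1000):
        p = rng.random(n)
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)
    p = rng.random(500) ** 3  # skewed small p-values
    assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


# -- significance trajectory ------------------------------------------------

def test_flat_significance_curve(rng):
    t = fit_group_trajectory(rng.normal(size=200), rng.uniform(8, 70, 200))
    grid = divergence_grid(t, t)
    ages, smooth, crossings = significance_trajectory(grid)
    assert np.allclose(smooth, 0.0) and crossings == []


def test_single_block_gives_two_crossings(rng):
    a1, a2 = rng.uniform(8, 70, 4000), rng.uniform(8, 70, 4000)
    y1 = rng.normal(size=4000) + 0.6 * np.exp(-(((a1 - 40) / 8.0) ** 2))
    g = divergence_grid(fit_group_trajectory(y1, a1),
                        fit_group_trajectory(rng.normal(size=4000), a2))
    assert len(g.windows) >= 1
    _, smooth, crossings = significance_trajectory(g)
    assert len(crossings) == 2


# -- longitudinal change rate ----------------------------------------------

@pytest.fixture(scope="module")
def followup_scans():
    cfg = SimConfig(
        seed=21, prev_width=1e6, prev_base=0.0,
        studies=(StudySpec("u", 8, 60, 3000, 0.5, 1),),
        followup_prob=(("u", 1.0, 3.0),),
        batch_shift_sd=0.0, batch_scale_sd=0.0,
    )
    scans, man = generate_cohort(cfg)
    return cfg, generate_followup(scans, cfg, man)


def test_change_rate_recovers_planted_slope(followup_scans):
    cfg, fu = followup_scans
    fu = fu.assign(logv=np.log(fu["hippocampus_l"]))
    coef, se, p = longitudinal_change_rate(fu, "logv")
    assert coef == pytest.approx(cfg.slope_diff, abs=0.0015)  # +-0.15%/yr
    assert p < 0.05


def test_change_rate_sign_flips_with_group_coding(followup_scans):
    _, fu = followup_scans
    fu = fu.assign(logv=np.log(fu["hippocampus_l"]))
    c1, _, _ = longitudinal_change_rate(fu, "logv", case_label="SUD")
    c2, _, _ = longitudinal_change_rate(fu, "logv", case_label="HC")
    assert c1 == pytest.approx(-c2, rel=1e-9)


def test_change_rate_null(rng):
    cfg = SimConfig(
        seed=22, prev_width=1e6, slope_diff=0.0,
        studies=(StudySpec("u", 8, 60, 2000, 0.5, 1),),
        followup_prob=(("u", 1.0, 3.0),),
        batch_shift_sd=0.0, batch_scale_sd=0.0,
    )
    scans, man = generate_cohort(cfg)
    fu = generate_followup(scans, cfg, man)
    fu = fu.assign(logv=np.log(fu["putamen_r"]))
    coef, se, _ = longitudinal_change_rate(fu, "logv")
    assert abs(coef) < 3 * se


def test_no_followups_rejected(uniform_cohort):
    _, scans, _ = uniform_cohort
    with pytest.raises(ValueError):
        longitudinal_change_rate(scans, "hippocampus_l")


# -- IVW meta ---------------------------------------------------------------

def test_ivw_closed_form():
    est, se = ivw_meta([1.0, 3.0], [1.0, 1.0])
    assert est == pytest.approx(2.0) and se == pytest.approx(np.sqrt(0.5))


def test_ivw_single_and_degenerate():
    assert ivw_meta([2.5], [0.3]) == (pytest.approx(2.5), pytest.approx(0.3))
    est, se = ivw_meta([1.0, 9.0], [0.0, 1.0])
    assert est == 1.0 and se == 0.0


def test_ivw_length_mismatch():
    with pytest.raises(ValueError):
        ivw_meta([1.0], [1.0, 2.0])


# -- consistency correlation ------------------------------------------------

def test_consistency_identical_and_reversed():
    ages = np.arange(8, 70, 0.5)
    z = np.sin(ages / 10)
    assert consistency_correlation(z, ages, z, ages) == pytest.approx(1.0)
    assert consistency_correlation(z, ages, -z, ages) == pytest.approx(-1.0)


def test_consistency_degrades_with_noise(rng):
    ages = np.arange(8, 70, 0.5)
    z = np.sin(ages / 10)
    rs = []
    for sd in (0.2, 2.0):
        vals = [consistency_correlation(z, ages, z + rng.normal(0, sd, len(z)),
                                        ages) for _ in range(20)]
        rs.append(np.mean(vals))
    assert 0 < rs[1] < rs[0] < 1


def test_consistency_needs_overlap():
    assert np.isnan(consistency_correlation([1, 2], [8, 9], [1, 2], [50, 51]))


# -- centile clustering -----------------------------------------------------

def test_planted_blocks_recovered(rng):
    n = 500
    f1, f2 = rng.normal(size=n), rng.normal(size=n)
    cols = {}
    for i in range(4):
        cols[f"a{i}"] = 0.9 * f1 + np.sqrt(1 - 0.81) * rng.normal(size=n)
    for i in range(4):
        cols[f"b{i}"] = 0.9 * f2 + np.sqrt(1 - 0.81) * rng.normal(size=n)
    labels, Z = cluster_centile_patterns(pd.DataFrame(cols), n_clusters=2)
    a_labels = {labels[f"a{i}"] for i in range(4)}
    b_labels = {labels[f"b{i}"] for i in range(4)}
    assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels


def test_single_roi_single_cluster():
    labels, Z = cluster_centile_patterns(pd.DataFrame({"a": [0.1, 0.5, 0.9]}))
    assert labels == {"a": 1}


def test_cluster_order_invariance(rng):
    df = pd.DataFrame(rng.normal(size=(100, 6)), columns=list("abcdef"))
    l1, _ = cluster_centile_patterns(df, n_clusters=3)
    l2, _ = cluster_centile_patterns(df[list("fedcba")], n_clusters=3)
    part1 = {frozenset(k for k, v in l1.items() if v == c) for c in set(l1.values())}
    part2 = {frozenset(k for k, v in l2.items() if v == c) for c in set(l2.values())}
    assert part1 == part2


def test_constant_column_dropped_with_warning(rng):
    df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50),
                       "c": np.ones(50)})
    with pytest.warns(UserWarning, match="constant"):
        labels, _ = cluster_centile_patterns(df, n_clusters=2)
    assert "c" not in labels
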