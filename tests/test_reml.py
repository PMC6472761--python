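"""REML engine: MME oracles, closed forms, likelihood properties, AIC/LRT."""

import numpy as np
import pytest

from mtme.design import ModelSpec, build_design
from mtme.reml import (CovarianceSet, aic_value, fit_reml, lrt,
                       reml_loglik, solve_mme)
from mtme.synthetic import simulate_trial

from conftest import assert_monotone_loglik, make_params


# ---------------------------------------------------------------------
# Henderson MME vs explicit GLS (V-inverse) oracle
# ---------------------------------------------------------------------

@pytest.mark.parametrize("traits,sigma_g,sigma_int,sigma_e", [
    (("T",), [[4.0]], [[2.0]], [[3.0]]),
    (("A", "B"), [[10.0, 8.0], [8.0, 40.0]],
     np.diag([4.0, 8.0]).tolist(), [[6.0, 5.0], [5.0, 30.0]]),
])
def test_blup_equals_gls_on_small_instance(traits, sigma_g, sigma_int,
                                           sigma_e):
    params = make_params(n_progeny=5, n_blocks=2, traits=traits,
                         means=[10.0] * len(traits),
                         sigma_g=np.array(sigma_g),
                         sigma_int=np.array(sigma_int),
                         sigma_e=np.array(sigma_e))
    table, _ = simulate_trial(params, seed=3)
    d = build_design(table, ModelSpec(traits))
    comps = CovarianceSet(np.array(sigma_g), np.array(sigma_int),
                          np.array(sigma_e))
    fit = solve_mme(d, comps)

    Z, W, X, y = d.Z.toarray(), d.W.toarray(), d.X.toarray(), d.y
    q, m = d.n_progeny, d.n_cells
    G = np.kron(comps.sigma_g, np.eye(q))
    D = np.kron(comps.sigma_int, np.eye(m))
    R = np.kron(comps.sigma_e, np.eye(d.n_plots))
    V = Z @ G @ Z.T + W @ D @ W.T + R
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    g = G @ Z.T @ Vi @ (y - X @ b)
    np.testing.assert_allclose(fit.blup_g.T.ravel(), g, atol=1e-8)
    np.testing.assert_allclose(fit.blue, b, atol=1e-8)


def test_full_shrinkage_limit(st_trial):
    """sigma_g -> 0 drives every progeny BLUP deviation to zero."""
    _, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    fit = solve_mme(d, CovarianceSet([[1e-10]], [[10.0]], [[20.0]]))
    assert np.abs(fit.blup_g).max() < 1e-6


def test_weak_shrinkage_limit_matches_progeny_means():
    """sigma_g >> sigma_e on balanced data: BLUP deviation ~ progeny mean
    minus the grand mean (fixed effects flat here)."""
    params = make_params(n_progeny=30)
    params.location_effects[:] = 0.0
    params.block_effects[:] = 0.0
    table, _ = simulate_trial(params, seed=13)
    d = build_design(table, ModelSpec(("DM",)))
    fit = solve_mme(d, CovarianceSet([[1e6]], [[1e-8]], [[20.0]]))
    means = table.data.groupby("progeny")["DM"].mean()
    dev = (means - table.data["DM"].mean()).to_numpy()
    np.testing.assert_allclose(fit.blup_g[:, 0], dev, atol=1e-3)


def test_blup_deviations_sum_to_zero(st_trial):
    _, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    fit = fit_reml(d, tol=1e-10)
    assert abs(fit.blup_g[:, 0].sum()) < 1e-5
    assert np.all(fit.pev_g >= 0)
    assert np.all(fit.pev_g[:, 0] <= fit.components.sigma_g[0, 0] + 1e-12)


# ---------------------------------------------------------------------
# Restricted likelihood
# ---------------------------------------------------------------------

def test_loglik_scaling_jacobian(st_trial):
    """Scaling y by c and all components by c^2 shifts logL by
    -(N - p) log c exactly."""
    _, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    comps = CovarianceSet([[30.0]], [[10.0]], [[20.0]])
    l0 = reml_loglik(d, comps)
    c = 3.7
    d2 = build_design(table, ModelSpec(("DM",)))
    d2.y = d.y * c
    comps2 = CovarianceSet([[30.0 * c**2]], [[10.0 * c**2]],
                           [[20.0 * c**2]])
    l1 = reml_loglik(d2, comps2)
    expected = l0 - (d.n_obs - 6) * np.log(c)
    assert l1 == pytest.approx(expected, abs=1e-6)


def test_reml_optimum_on_grid():
    """On a balanced RCBD layout the restricted likelihood over a grid is
    maximal at the closed-form ANOVA-REML estimates."""
    params = make_params(n_progeny=25, n_locations=1, sigma_int=[[0.0]])
    table, _ = simulate_trial(params, seed=17)
    d = build_design(table, ModelSpec(("DM",), include_interaction=False))
    sg_hat, se_hat = _anova_reml(table)
    best = reml_loglik(d, CovarianceSet([[sg_hat]], None, [[se_hat]]))
    for fg in (0.8, 0.9, 1.1, 1.25):
        for fe in (0.8, 0.9, 1.1, 1.25):
            if fg == 1.0 and fe == 1.0:
                continue
            other = reml_loglik(
                d, CovarianceSet([[sg_hat * fg]], None, [[se_hat * fe]]))
            assert other < best


def _anova_reml(table):
    """Closed-form REML for a balanced RCBD with fixed blocks and random
    genotypes: sigma_e = MSE, sigma_g = (MSG - MSE)/r."""
    df = table.data
    r = df["block"].nunique()
    q = df["progeny"].nunique()
    y = df["DM"].to_numpy()
    gm = y.mean()
    gmeans = df.groupby("progeny")["DM"].mean()
    bmeans = df.groupby("block")["DM"].mean()
    ss_g = r * ((gmeans - gm) ** 2).sum()
    ss_b = q * ((bmeans - gm) ** 2).sum()
    ss_tot = ((y - gm) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_b
    msg = ss_g / (q - 1)
    mse = ss_e / ((q - 1) * (r - 1))
    return (msg - mse) / r, mse


def test_fit_reml_matches_anova_closed_form():
    params = make_params(n_progeny=30, n_locations=1, sigma_int=[[0.0]])
    table, _ = simulate_trial(params, seed=19)
    d = build_design(table, ModelSpec(("DM",), include_interaction=False))
    fit = fit_reml(d, tol=1e-14, max_iter=20000)
    sg_hat, se_hat = _anova_reml(table)
    assert fit.components.sigma_g[0, 0] == pytest.approx(sg_hat, abs=1e-6)
    assert fit.components.sigma_e[0, 0] == pytest.approx(se_hat, abs=1e-6)
    assert_monotone_loglik(fit)


def test_loglik_at_estimate_beats_truth(st_trial):
    params, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    fit = fit_reml(d, tol=1e-10)
    truth = CovarianceSet(params.sigma_g, params.sigma_int, params.sigma_e)
    assert fit.logL >= reml_loglik(d, truth) - 1e-8
    assert_monotone_loglik(fit)
    assert fit.converged


def test_st_mt_reduction_on_diagonal_truth():
    params = make_params(n_progeny=60, traits=("A", "B"),
                         means=[50.0, 100.0], sigma_g=np.diag([10.0, 40.0]),
                         sigma_int=np.diag([4.0, 8.0]),
                         sigma_e=np.diag([6.0, 30.0]))
    table, _ = simulate_trial(params, seed=7)
    fmt = fit_reml(build_design(table, ModelSpec(("A", "B"))), tol=1e-13,
                   max_iter=20000)
    assert_monotone_loglik(fmt)
    for k, trait in enumerate(("A", "B")):
        fst = fit_reml(build_design(table, ModelSpec((trait,))), tol=1e-13,
                       max_iter=20000)
        for comp in ("sigma_g", "sigma_int", "sigma_e"):
            mt = getattr(fmt.components, comp)[k, k]
            st = getattr(fst.components, comp)[0, 0]
            assert mt == pytest.approx(st, rel=1e-4)


def test_fit_with_missing_data_runs(st_trial):
    params = make_params(n_progeny=30, missing_rate=0.08)
    table, _ = simulate_trial(params, seed=23)
    d = build_design(table, ModelSpec(("DM",)))
    fit = fit_reml(d, tol=1e-9)
    assert fit.converged
    assert_monotone_loglik(fit)
    assert fit.components.sigma_g[0, 0] > 0


# ---------------------------------------------------------------------
# Model comparison arithmetic
# ---------------------------------------------------------------------

def test_aic_from_reported_deviances():
    assert aic_value(6907.569, 3) == pytest.approx(6913.569)
    assert aic_value(7048.743, 2) == pytest.approx(7052.743)
    assert aic_value(123.4, 0) == 123.4
    with pytest.raises(ValueError):
        aic_value(1.0, -1)


def test_lrt_from_reported_deviances():
    lam, p = lrt(7048.74, 6907.57)
    assert lam == pytest.approx(141.17)
    assert p < 0.01
    lam2, _ = lrt(7010.14, 6907.57)
    assert lam2 == pytest.approx(102.57)
    lam0, p0 = lrt(5.0, 5.0)
    assert lam0 == 0.0 and p0 == 1.0


def test_variance_parameter_counting():
    st_full = CovarianceSet([[1.0]], [[1.0]], [[1.0]])
    st_red = CovarianceSet(None, [[1.0]], [[1.0]])
    mt_full = CovarianceSet(np.eye(3), np.eye(3), np.eye(3))
    assert st_full.n_varparams() == 3
    assert st_red.n_varparams() == 2
    assert mt_full.n_varparams() == 18      # 3 * t(t+1)/2 with t=3
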