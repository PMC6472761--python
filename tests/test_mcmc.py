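"""Gibbs sampler, chain diagnostics, DIC and posterior summaries."""

import numpy as np
import pytest

from mtme.design import ModelSpec, build_design
from mtme.mcmc import (IGPrior, IWPrior, McmcOpts, PriorError, PriorSpec,
                       chain_diagnostics, default_weak_priors, dic_value,
                       hpd_interval, posterior_summary, run_mcmc)
from mtme.synthetic import simulate_trial

from conftest import make_params


@pytest.fixture(scope="module")
def st_samples(st_trial):
    """One moderate single-trait run shared across diagnostic tests."""
    _, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    sm = run_mcmc(d, default_weak_priors(1),
                  McmcOpts(n_iter=4000, burn_in=1500, thin=3, seed=77))
    return d, sm


def test_stored_sample_counting(st_trial):
    assert McmcOpts(n_iter=1000, burn_in=500, thin=5, seed=1).n_stored == 100
    assert McmcOpts(n_iter=1001, burn_in=500, thin=5, seed=1).n_stored == 100
    with pytest.raises(ValueError):
        McmcOpts(n_iter=100, burn_in=100, thin=5, seed=1)


def test_seed_determinism(st_trial):
    _, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    opts = McmcOpts(n_iter=600, burn_in=200, thin=2, seed=5)
    s1 = run_mcmc(d, default_weak_priors(1), opts, store_deviance=False)
    s2 = run_mcmc(d, default_weak_priors(1), opts, store_deviance=False)
    assert np.array_equal(s1.sigma_g_chain, s2.sigma_g_chain)
    assert np.array_equal(s1.g_chain, s2.g_chain)


def test_conjugate_closed_form():
    """One random effect observed almost directly (residual variance pinned
    near zero): the sigma_g posterior matches the analytic inverse-gamma
    obtained by integrating the flat mean out."""
    params = make_params(n_progeny=150, n_locations=1, n_blocks=1,
                         means=[0.0], sigma_g=[[25.0]], sigma_int=[[0.0]],
                         sigma_e=[[1e-4]])
    table, _ = simulate_trial(params, seed=9)
    d = build_design(table, ModelSpec(("DM",), include_interaction=False))
    a0, b0 = 2.0, 30.0
    prior = PriorSpec(IGPrior(a0, b0), None,
                      IGPrior(1e4, 1e4 * 1e-4))        # pins sigma_e ~ 1e-4
    sm = run_mcmc(d, prior, McmcOpts(n_iter=6000, burn_in=1000, thin=2,
                                     seed=6), store_deviance=False)
    y = d.y
    S = float(((y - y.mean()) ** 2).sum())
    a_post, b_post = a0 + (150 - 1) / 2, b0 + S / 2
    analytic_mean = b_post / (a_post - 1)
    analytic_sd = analytic_mean / np.sqrt(a_post - 2)
    chain = sm.sigma_g_chain[:, 0, 0]
    assert chain.mean() == pytest.approx(analytic_mean,
                                         abs=4 * analytic_sd / np.sqrt(200))
    assert chain.std() == pytest.approx(analytic_sd, rel=0.2)


def test_multitrait_sampler_runs_and_draws_psd(two_trait_trial):
    _, table, _ = two_trait_trial
    d = build_design(table, ModelSpec(("A", "B")))
    sm = run_mcmc(d, default_weak_priors(2),
                  McmcOpts(n_iter=800, burn_in=300, thin=2, seed=3),
                  store_deviance=False)
    for s in range(sm.n_stored):
        for chain in (sm.sigma_g_chain, sm.sigma_int_chain,
                      sm.sigma_e_chain):
            assert np.linalg.eigvalsh(chain[s]).min() > -1e-10


def test_missing_cells_are_augmented(two_trait_trial):
    params, _, _ = two_trait_trial
    params2 = make_params(n_progeny=30, traits=("A", "B"),
                          means=[50.0, 100.0], sigma_g=params.sigma_g,
                          sigma_int=params.sigma_int, sigma_e=params.sigma_e,
                          missing_rate=0.05)
    table, _ = simulate_trial(params2, seed=31)
    d = build_design(table, ModelSpec(("A", "B")), keep_missing=True)
    sm = run_mcmc(d, default_weak_priors(2),
                  McmcOpts(n_iter=600, burn_in=200, thin=2, seed=8),
                  store_deviance=False)
    assert sm.n_stored == 200
    assert np.isfinite(sm.sigma_g_chain).all()
    # multi-trait partial plots without the mask are rejected
    d_dropped = build_design(table, ModelSpec(("A", "B")))
    with pytest.raises(ValueError, match="keep_missing"):
        run_mcmc(d_dropped, default_weak_priors(2),
                 McmcOpts(n_iter=200, burn_in=50, thin=1, seed=1))


def test_improper_priors_rejected():
    with pytest.raises(PriorError):
        IWPrior(np.eye(2), 0.5)
    with pytest.raises(PriorError):
        IGPrior(-1.0, 1.0)


def test_prior_scale_insensitivity(st_trial):
    """Doubling the weak prior scale moves posterior means of sigma_g by
    well under 2% (common random numbers isolate the prior effect)."""
    _, table, _ = st_trial
    d = build_design(table, ModelSpec(("DM",)))
    opts = McmcOpts(n_iter=2000, burn_in=800, thin=2, seed=12)
    s1 = run_mcmc(d, PriorSpec(IGPrior(0.001, 0.001), IGPrior(0.001, 0.001),
                               IGPrior(0.001, 0.001)), opts,
                  store_deviance=False)
    s2 = run_mcmc(d, PriorSpec(IGPrior(0.002, 0.002), IGPrior(0.002, 0.002),
                               IGPrior(0.002, 0.002)), opts,
                  store_deviance=False)
    m1 = s1.sigma_g_chain.mean()
    m2 = s2.sigma_g_chain.mean()
    assert abs(m2 - m1) / m1 < 0.02


# ---------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------

def test_geweke_calibration():
    """|z| < 1.96 for about 95% of i.i.d.-normal chains."""
    rng = np.random.default_rng(2024)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        z = chain_diagnostics(rng.standard_normal(600)).geweke_z
        hits += abs(z) < 1.96
    assert 0.93 <= hits / n_rep <= 0.97


def test_hpd_width_on_uniform():
    rng = np.random.default_rng(1)
    x = rng.random(100_000)
    lo, hi = hpd_interval(x, 0.95)
    assert hi - lo == pytest.approx(0.95, abs=0.01)


def test_hpd_shortest_interval_on_skewed_chain():
    """On a lognormal chain the HPD hugs the bulk near zero and is shorter
    than the equal-tail interval; cross-checked against arviz."""
    rng = np.random.default_rng(3)
    x = np.exp(rng.standard_normal(50_000))
    lo, hi = hpd_interval(x, 0.95)
    eq = np.percentile(x, [2.5, 97.5])
    assert (hi - lo) < (eq[1] - eq[0])
    az = pytest.importorskip("arviz")
    ref = az.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(float(ref[0]), abs=0.02)
    assert hi == pytest.approx(float(ref[1]), abs=0.1)


def test_constant_chain_flagged():
    d = chain_diagnostics(np.full(500, 0.5))
    assert np.isnan(d.geweke_z)
    assert d.hpd == (0.5, 0.5)
    assert any("constant" in m for m in d.messages)


# ---------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------

def test_dic_identity_and_value(st_samples):
    d, sm = st_samples
    res = dic_value(sm, d)
    assert res.dic == pytest.approx(res.Dbar + res.pD, abs=1e-10)
    assert res.dic == pytest.approx(res.Dhat + 2 * res.pD, abs=1e-10)
    assert res.pD > 0                      # healthy run on real signal


def test_degenerate_posterior_gives_zero_pd(st_samples):
    d, sm = st_samples
    import copy
    frozen = copy.copy(sm)
    S = sm.n_stored
    frozen.sigma_g_chain = np.repeat(sm.sigma_g_chain[:1], S, axis=0)
    frozen.sigma_int_chain = np.repeat(sm.sigma_int_chain[:1], S, axis=0)
    frozen.sigma_e_chain = np.repeat(sm.sigma_e_chain[:1], S, axis=0)
    frozen.beta_chain = np.repeat(sm.beta_chain[:1], S, axis=0)
    from mtme.reml import _MMEWork, marginal_deviance
    from mtme.design import drop_masked_rows
    dev = marginal_deviance(_MMEWork(drop_masked_rows(d)),
                            frozen.component_draw(0), frozen.beta_chain[0])
    frozen.deviance_chain = np.full(S, dev)
    res = dic_value(frozen, d)
    assert res.pD == pytest.approx(0.0, abs=1e-8)
    assert res.dic == pytest.approx(res.Dhat, abs=1e-8)


# ---------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------

def test_posterior_summary_heritability(st_samples):
    _, sm = st_samples

    def h2(draw):
        sg = draw.sigma_g[0, 0]
        return sg / (sg + draw.sigma_int[0, 0] / 2
                     + draw.sigma_e[0, 0] / 6)

    res = posterior_summary(sm, h2)
    assert 0 < res.hpd[0] < res.median < res.hpd[1] < 1
    assert res.mean == pytest.approx(res.median, abs=0.05)
    # draw-wise transform vs transform of means (Jensen gap exists)
    mean_comp = sm.posterior_mean_components()
    assert res.mean != pytest.approx(h2(mean_comp), abs=1e-12)


def test_lognormal_mode_median_mean_ordering():
    rng = np.random.default_rng(8)
    vals = np.exp(rng.standard_normal(4000))

    class Fake:
        n_stored = len(vals)

        def component_draw(self, s):
            return vals[s]

    res = posterior_summary(Fake(), lambda v: float(v))
    assert res.mode < res.median < res.mean
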