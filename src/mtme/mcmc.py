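"""Bayesian engine: blocked Gibbs sampler, chain diagnostics, DIC, summaries.

The sampler alternates conjugate conditional draws:

1. joint multivariate-normal draw of all fixed and random effects given the
   covariance matrices (fixed effects get a flat normal prior with large
   variance);
2. data augmentation of any masked phenotype cells from their conditional
   normal given the current effects and residual covariance (keeps the
   residual update conjugate on unbalanced data);
3. inverse-Wishart draws of Sigma_g, Sigma_int and Sigma_e given the
   current effects/residuals (independent inverse-gamma in the single-trait
   case).

The deviance recorded for DIC is the observed-data Gaussian deviance given
(fixed effects, covariance matrices) with the random effects integrated out
analytically; DIC values are therefore comparable between fits of this
package but not with samplers that condition on the latent effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
from scipy.stats import gaussian_kde, invgamma, invwishart

from .design import DesignSet, drop_masked_rows
from .reml import CovarianceSet, _MMEWork, marginal_deviance


class PriorError(ValueError):
    """Improper or mis-dimensioned prior specification."""


@dataclass
class IWPrior:
    """Inverse-Wishart prior for a trait-by-trait covariance matrix."""

    scale: np.ndarray
    df: float

    def __post_init__(self) -> None:
        self.scale = np.atleast_2d(np.asarray(self.scale, float))
        t = self.scale.shape[0]
        if self.df <= t - 1:
            raise PriorError(f"IW df must exceed dim-1 ({t - 1}); got {self.df}")
        if np.linalg.eigvalsh(self.scale).min() < 0:
            raise PriorError("IW scale matrix must be PSD")

    def posterior_draw(self, S: np.ndarray, n: int,
                       rng: np.random.Generator) -> np.ndarray:
        return invwishart.rvs(df=self.df + n, scale=self.scale + S,
                              random_state=rng)


@dataclass
class IGPrior:
    """Inverse-gamma prior for a scalar variance component."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise PriorError("IG shape and scale must be positive")

    def posterior_draw(self, ssq: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
        draw = invgamma.rvs(self.shape + 0.5 * n,
                            scale=self.scale + 0.5 * ssq, random_state=rng)
        return np.atleast_2d(draw)


@dataclass
class PriorSpec:
    """Priors for the three covariance blocks plus the fixed-effect
    normal-prior variance (large => effectively flat)."""

    sigma_g_prior: IWPrior | IGPrior | None
    sigma_int_prior: IWPrior | IGPrior | None
    sigma_e_prior: IWPrior | IGPrior
    fixed_effect_variance: float = 1e8


def default_weak_priors(n_traits: int) -> PriorSpec:
    """Weak default priors for the covariance blocks.

    Single-trait: IG(0.001, 0.001).  Multi-trait: IW(scale=I, df=t+1).
    The identity scale matters: an IW prior with a near-zero scale matrix
    places unbounded density on singular covariance matrices and the Gibbs
    chain can get trapped near a degenerate Sigma (effects drawn inside the
    deficient subspace keep the sufficient statistic singular); the
    tr(Sigma^-1) penalty of a unit scale removes that trap while remaining
    negligible against the data at trial scale.
    """
    if n_traits == 1:
        mk = lambda: IGPrior(0.001, 0.001)
    else:
        mk = lambda: IWPrior(np.eye(n_traits), float(n_traits) + 1.0)
    return PriorSpec(mk(), mk(), mk())


@dataclass
class McmcOpts:
    """MCMC schedule.  Stored samples = floor((n_iter - burn_in)/thin)."""

    n_iter: int = 20000
    burn_in: int = 10000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Stored MCMC draws of covariance matrices, effects and deviance."""

    sigma_g_chain: np.ndarray | None      # (S, t, t)
    sigma_int_chain: np.ndarray | None
    sigma_e_chain: np.ndarray             # (S, t, t)
    g_chain: np.ndarray | None            # (S, n_progeny, t)
    beta_chain: np.ndarray                # (S, p_X)
    deviance_chain: np.ndarray | None
    opts_used: McmcOpts
    prior_used: PriorSpec
    trait_names: tuple[str, ...] = ()
    progeny_ids: list[str] = field(default_factory=list)

    @property
    def n_stored(self) -> int:
        return self.sigma_e_chain.shape[0]

    def component_draw(self, s: int) -> CovarianceSet:
        g = None if self.sigma_g_chain is None else self.sigma_g_chain[s]
        i = None if self.sigma_int_chain is None else self.sigma_int_chain[s]
        return CovarianceSet(g, i, self.sigma_e_chain[s])

    def posterior_mean_components(self) -> CovarianceSet:
        g = (None if self.sigma_g_chain is None
             else self.sigma_g_chain.mean(axis=0))
        i = (None if self.sigma_int_chain is None
             else self.sigma_int_chain.mean(axis=0))
        return CovarianceSet(g, i, self.sigma_e_chain.mean(axis=0))


class _GibbsWork:
    """Precomputed design structures for the Gibbs sweeps.

    Requires every plot to carry all traits in the design rows: build the
    design with ``keep_missing=True`` for multi-trait data with missing
    cells (masked rows are imputed).  Single-trait designs may simply drop
    missing rows.
    """

    def __init__(self, design: DesignSet):
        t = design.n_traits
        X, Z, W = design.X, design.Z, design.W
        self.p_X = X.shape[1]
        self.q = design.n_progeny if Z is not None else 0
        self.m = design.n_cells if W is not None else 0
        self.has_g, self.has_i = Z is not None, W is not None
        blocks = [X] + [b for b in (Z, W) if b is not None]
        self.T = sp.hstack(blocks, format="csr")
        self.P = self.T.shape[1]
        self.g_off = self.p_X
        self.i_off = self.p_X + (self.q * t if self.has_g else 0)
        self.t = t

        n_obs = design.n_obs
        if t > 1:
            if n_obs != t * design.n_plots:
                raise ValueError(
                    "multi-trait Gibbs sampling needs complete plots; build "
                    "the design with keep_missing=True so missing cells can "
                    "be imputed")
            self.n_plots = design.n_plots
            # trait-major rows all aligned on the same plot order
            self.rows_by_trait = [
                np.arange(k * self.n_plots, (k + 1) * self.n_plots)
                for k in range(t)]
        else:
            self.n_plots = n_obs
            self.rows_by_trait = [np.arange(n_obs)]

        self.Trows = [self.T[r].tocsr() for r in self.rows_by_trait]
        self.Kdense = {}
        for a in range(t):
            for b in range(a, t):
                self.Kdense[(a, b)] = (
                    self.Trows[a].T @ self.Trows[b]).toarray()

        ar = np.arange
        self.diag_idx = []
        if self.has_g:
            self.g_idx = [(self.g_off + s * self.q + ar(self.q))
                          for s in range(t)]
        if self.has_i:
            self.i_idx = [(self.i_off + s * self.m + ar(self.m))
                          for s in range(t)]

    def assemble(self, sigma_e: np.ndarray, sigma_g, sigma_int,
                 fixed_prec: float, y: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        t = self.t
        Rinv = np.linalg.inv(sigma_e)
        M = np.zeros((self.P, self.P))
        rhs = np.zeros(self.P)
        for a in range(t):
            ya = y[self.rows_by_trait[a]]
            for b in range(a, t):
                K = self.Kdense[(a, b)]
                c = Rinv[a, b]
                if a == b:
                    M += c * K
                    rhs += c * (self.Trows[a].T @ ya)
                else:
                    M += c * (K + K.T)
                    rhs += c * (self.Trows[a].T @ y[self.rows_by_trait[b]])
                    rhs += c * (self.Trows[b].T @ ya)
        M[np.arange(self.p_X), np.arange(self.p_X)] += fixed_prec
        if self.has_g:
            ginv = np.linalg.inv(sigma_g)
            for s in range(t):
                for u in range(t):
                    M[self.g_idx[s], self.g_idx[u]] += ginv[s, u]
        if self.has_i:
            iinv = np.linalg.inv(sigma_int)
            for s in range(t):
                for u in range(t):
                    M[self.i_idx[s], self.i_idx[u]] += iinv[s, u]
        return M, rhs


def run_mcmc(design: DesignSet, prior: PriorSpec | None = None,
             opts: McmcOpts | None = None,
             store_deviance: bool = True) -> PosteriorSamples:
    """Blocked Gibbs sampler for the MTME mixed model.

    Deterministic given ``opts.seed``.  Masked rows of the design (built
    with ``keep_missing=True``) are treated as missing data and imputed
    each sweep; the deviance chain is always computed on observed rows
    only.
    """
    t = design.n_traits
    if prior is None:
        prior = default_weak_priors(t)
    if opts is None:
        opts = McmcOpts()
    for name, pr, needed in (("sigma_g", prior.sigma_g_prior, design.Z is not None),
                             ("sigma_int", prior.sigma_int_prior, design.W is not None),
                             ("sigma_e", prior.sigma_e_prior, True)):
        if needed and pr is None:
            raise PriorError(f"prior for {name} is required by this design")
        if pr is not None and isinstance(pr, IWPrior) \
                and pr.scale.shape[0] != t:
            raise PriorError(f"{name} IW prior dimension mismatch")
        if t > 1 and needed and isinstance(pr, IGPrior):
            raise PriorError(f"{name}: IG prior is single-trait only")

    rng = np.random.default_rng(opts.seed)
    work = _GibbsWork(design)
    mask = design.missing_mask.copy()
    y = design.y.copy()
    # initialise masked cells at their trait mean
    if mask.any():
        for k in range(t):
            rows = work.rows_by_trait[k]
            mk = mask[rows]
            y[rows[mk]] = np.nanmean(y[rows[~mk]])

    obs_work = None
    if store_deviance:
        obs_work = _MMEWork(drop_masked_rows(design))

    # start components at the phenotypic covariance split equally
    from .reml import default_init
    comps0 = default_init(drop_masked_rows(design))
    sigma_e = comps0.sigma_e.copy()
    sigma_g = comps0.sigma_g.copy() if work.has_g else None
    sigma_int = comps0.sigma_int.copy() if work.has_i else None
    fixed_prec = 1.0 / prior.fixed_effect_variance

    S = opts.n_stored
    out_g = np.empty((S, t, t)) if work.has_g else None
    out_i = np.empty((S, t, t)) if work.has_i else None
    out_e = np.empty((S, t, t))
    out_eff = np.empty((S, work.q, t)) if work.has_g else None
    out_b = np.empty((S, work.p_X))
    out_dev = np.empty(S) if store_deviance else None

    n_plots = work.n_plots
    s_out = 0
    for it in range(1, opts.n_iter + 1):
        # 1. effects | y, Sigma
        M, rhs = work.assemble(sigma_e, sigma_g, sigma_int, fixed_prec, y)
        try:
            cf = la.cho_factor(M, lower=True, check_finite=False)
        except la.LinAlgError:
            M[np.diag_indices_from(M)] += 1e-8 * np.trace(M) / M.shape[0]
            cf = la.cho_factor(M, lower=True, check_finite=False)
        mu = la.cho_solve(cf, rhs, check_finite=False)
        z = rng.standard_normal(work.P)
        theta = mu + la.solve_triangular(cf[0], z, lower=True, trans="T",
                                         check_finite=False)
        fitted = work.T @ theta

        # 2. impute masked cells | effects, Sigma_e
        if mask.any():
            resid_mat = (y - fitted)[
                np.concatenate(work.rows_by_trait)].reshape(t, n_plots).T
            miss_mat = mask[np.concatenate(work.rows_by_trait)] \
                .reshape(t, n_plots).T
            pat_key = miss_mat.astype(np.int64) @ (1 << np.arange(t))
            for key in np.unique(pat_key):
                if key == 0:
                    continue
                plots = np.flatnonzero(pat_key == key)
                mis = [k for k in range(t) if key >> k & 1]
                obs = [k for k in range(t) if not key >> k & 1]
                if obs:
                    Soo = sigma_e[np.ix_(obs, obs)]
                    Smo = sigma_e[np.ix_(mis, obs)]
                    A = Smo @ np.linalg.inv(Soo)
                    cond_mean = resid_mat[np.ix_(plots, obs)] @ A.T
                    cond_cov = sigma_e[np.ix_(mis, mis)] - A @ Smo.T
                else:
                    cond_mean = np.zeros((len(plots), len(mis)))
                    cond_cov = sigma_e
                w, v = np.linalg.eigh(0.5 * (cond_cov + cond_cov.T))
                root = v * np.sqrt(np.clip(w, 0, None))
                draw = cond_mean + rng.standard_normal(
                    (len(plots), len(mis))) @ root.T
                for j, k in enumerate(mis):
                    rows = work.rows_by_trait[k][plots]
                    y[rows] = fitted[rows] + draw[:, j]

        # 3-5. covariance blocks | effects
        if work.has_g:
            G = theta[work.g_off:work.g_off + work.q * t] \
                .reshape(t, work.q).T
            if t == 1 and isinstance(prior.sigma_g_prior, IGPrior):
                sigma_g = prior.sigma_g_prior.posterior_draw(
                    float(G.ravel() @ G.ravel()), work.q, rng)
            else:
                sigma_g = np.atleast_2d(prior.sigma_g_prior.posterior_draw(
                    G.T @ G, work.q, rng))
        if work.has_i:
            I_ = theta[work.i_off:work.i_off + work.m * t] \
                .reshape(t, work.m).T
            if t == 1 and isinstance(prior.sigma_int_prior, IGPrior):
                sigma_int = prior.sigma_int_prior.posterior_draw(
                    float(I_.ravel() @ I_.ravel()), work.m, rng)
            else:
                sigma_int = np.atleast_2d(
                    prior.sigma_int_prior.posterior_draw(
                        I_.T @ I_, work.m, rng))
        resid = y - fitted
        if t == 1 and isinstance(prior.sigma_e_prior, IGPrior):
            sigma_e = prior.sigma_e_prior.posterior_draw(
                float(resid @ resid), n_plots, rng)
        else:
            E = resid[np.concatenate(work.rows_by_trait)] \
                .reshape(t, n_plots).T
            sigma_e = np.atleast_2d(prior.sigma_e_prior.posterior_draw(
                E.T @ E, n_plots, rng))

        # store
        if it > opts.burn_in and (it - opts.burn_in) % opts.thin == 0:
            out_e[s_out] = sigma_e
            if work.has_g:
                out_g[s_out] = sigma_g
                out_eff[s_out] = theta[work.g_off:work.g_off + work.q * t] \
                    .reshape(t, work.q).T
            if work.has_i:
                out_i[s_out] = sigma_int
            beta = theta[:work.p_X]
            out_b[s_out] = beta
            if store_deviance:
                comps = CovarianceSet(
                    sigma_g if work.has_g else None,
                    sigma_int if work.has_i else None, sigma_e)
                out_dev[s_out] = marginal_deviance(obs_work, comps, beta)
            s_out += 1

    return PosteriorSamples(
        sigma_g_chain=out_g, sigma_int_chain=out_i, sigma_e_chain=out_e,
        g_chain=out_eff, beta_chain=out_b, deviance_chain=out_dev,
        opts_used=opts, prior_used=prior, trait_names=design.trait_names,
        progeny_ids=design.progeny_ids,
    )


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero, via Bartlett-windowed
    autocovariances with lag window ~ sqrt(n)."""
    n = len(x)
    x = x - x.mean()
    L = max(1, int(np.sqrt(n)))
    acov = np.correlate(x, x, mode="full")[n - 1:n + L] / n
    w = 1.0 - np.arange(1, L + 1) / (L + 1.0)
    return float(acov[0] + 2.0 * (w * acov[1:]).sum())


def hpd_interval(chain: np.ndarray, prob: float = 0.95
                 ) -> tuple[float, float]:
    """Shortest empirical interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(chain, float))
    n = len(x)
    k = max(1, int(np.floor(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[:n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS from the initial-positive autocorrelation sequence."""
    x = np.asarray(chain, float)
    n = len(x)
    x = x - x.mean()
    v = float(x @ x) / n
    if v == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (n * v)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@dataclass
class ChainDiagnostics:
    geweke_z: float
    hpd: tuple[float, float]
    ess: float
    messages: list[str] = field(default_factory=list)


def chain_diagnostics(chain: np.ndarray, prob: float = 0.95,
                      first: float = 0.1, last: float = 0.5
                      ) -> ChainDiagnostics:
    """Geweke convergence z-score, HPD interval and effective sample size.

    Geweke compares the means of the first ``first`` and last ``last``
    fractions of the chain, with variances from the spectral density at
    zero.  A constant chain yields an undefined (NaN) z and a degenerate
    point HPD.
    """
    x = np.asarray(chain, float)
    if len(x) < 100:
        raise ValueError("chain too short for diagnostics (need >= 100)")
    msgs: list[str] = []
    if np.ptp(x) == 0.0:
        return ChainDiagnostics(
            geweke_z=float("nan"), hpd=(float(x[0]), float(x[0])),
            ess=float(len(x)), messages=["constant chain: Geweke undefined"])
    n = len(x)
    a = x[: int(first * n)]
    b = x[-int(last * n):]
    var = _spectral_density_zero(a) / len(a) + _spectral_density_zero(b) / len(b)
    z = float((a.mean() - b.mean()) / np.sqrt(var))
    ess = effective_sample_size(x)
    if ess < 100:
        msgs.append(f"low effective sample size ({ess:.0f})")
    return ChainDiagnostics(geweke_z=z, hpd=hpd_interval(x, prob), ess=ess,
                            messages=msgs)


@dataclass
class DicResult:
    dic: float
    pD: float
    Dbar: float
    Dhat: float
    messages: list[str] = field(default_factory=list)


def dic_value(samples: PosteriorSamples, design: DesignSet) -> DicResult:
    """Deviance information criterion: DIC = Dhat + 2 pD = Dbar + pD,
    with Dbar the posterior-mean deviance and Dhat the deviance at the
    posterior means of (fixed effects, covariance matrices)."""
    if samples.deviance_chain is None:
        raise ValueError("samples were run with store_deviance=False")
    obs_work = _MMEWork(drop_masked_rows(design))
    Dbar = float(samples.deviance_chain.mean())
    Dhat = marginal_deviance(obs_work,
                             samples.posterior_mean_components(),
                             samples.beta_chain.mean(axis=0))
    pD = Dbar - Dhat
    msgs = []
    if pD < 0:
        msgs.append(f"negative pD ({pD:.3g}): poor mixing or strong "
                    "posterior skew; DIC unreliable")
    return DicResult(dic=Dhat + 2.0 * pD, pD=pD, Dbar=Dbar, Dhat=Dhat,
                     messages=msgs)


@dataclass
class PosteriorSummary:
    mode: float
    mean: float
    median: float
    hpd: tuple[float, float]


def posterior_summary(samples: PosteriorSamples, quantity,
                      prob: float = 0.95) -> PosteriorSummary:
    """Summaries of a scalar derived parameter, computed draw-wise.

    ``quantity`` maps a :class:`~mtme.reml.CovarianceSet` draw to a scalar
    (e.g. a heritability transform).  The transform is applied to every
    stored draw and the summaries are computed on the transformed chain;
    the mode is the peak of a Gaussian KDE (Silverman bandwidth).
    """
    vals = np.array([quantity(samples.component_draw(s))
                     for s in range(samples.n_stored)], float)
    if np.ptp(vals) == 0.0:
        v = float(vals[0])
        return PosteriorSummary(v, v, v, (v, v))
    kde = gaussian_kde(vals)          # Silverman-type default bandwidth
    grid = np.linspace(vals.min(), vals.max(), 512)
    mode = float(grid[np.argmax(kde(grid))])
    return PosteriorSummary(mode=mode, mean=float(vals.mean()),
                            median=float(np.median(vals)),
                            hpd=hpd_interval(vals, prob))
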