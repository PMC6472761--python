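"""Frequentist engine: EM-REML variance components, Henderson MME, AIC, LRT.

The mixed model is y = Xb + Zg + Wi + e with unstructured trait-by-trait
covariance matrices Sigma_g (progeny), Sigma_int (progeny-by-location
interaction) and Sigma_e (plot residual, correlated across traits within a
plot, independent across plots).  In the stacked trait-major design the
random-effect covariances are Kronecker products Sigma (x) I.

Variance components are estimated by EM-REML: each iteration solves
Henderson's mixed-model equations at the current components and updates
each Sigma from the conditional expectation of its effects' outer products.
The restricted log-likelihood is monotone non-decreasing along the EM path,
which the test suite asserts on every fit; an optional Aitken-accelerated
step is only accepted when it does not break that monotonicity.

The restricted log-likelihood uses the standard mixed-model identity

    -2 logL_R = (N - p) log 2pi + log|R| + log|G| + log|M| + y'Py,

with M the MME coefficient matrix and p = rank(X); absolute values follow
this constant convention (software packages differ by constants, so only
likelihood differences are comparable across implementations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
from scipy.stats import chi2

from .design import DesignSet

_LOG2PI = float(np.log(2.0 * np.pi))


class NumericalError(RuntimeError):
    """Singular or indefinite system in the mixed-model equations."""


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    floor = eps * max(w.max(), 1e-300)
    if w.min() >= floor:
        return mat
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


@dataclass
class CovarianceSet:
    """Trait-by-trait covariance matrices of the three random terms.

    Scalars are accepted and stored as 1x1 matrices.  A term excluded from
    the model (reduced fits) may be ``None``.
    """

    sigma_g: np.ndarray | None
    sigma_int: np.ndarray | None
    sigma_e: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_e = np.atleast_2d(np.asarray(self.sigma_e, float))
        for name in ("sigma_g", "sigma_int"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, float))
                if v.shape != self.sigma_e.shape:
                    raise ValueError(f"{name} dimension {v.shape} != "
                                     f"sigma_e {self.sigma_e.shape}")
                setattr(self, name, v)

    @property
    def n_traits(self) -> int:
        return self.sigma_e.shape[0]

    def n_varparams(self) -> int:
        """Count of free variance-covariance parameters: each included
        unstructured block contributes t(t+1)/2 (fixed effects excluded)."""
        t = self.n_traits
        per = t * (t + 1) // 2
        return per * sum(m is not None
                         for m in (self.sigma_g, self.sigma_int, self.sigma_e))

    def copy(self) -> "CovarianceSet":
        cp = lambda m: None if m is None else m.copy()
        return CovarianceSet(cp(self.sigma_g), cp(self.sigma_int),
                             self.sigma_e.copy())


@dataclass
class FreqFit:
    """REML/BLUP fit: components, effects, PEV and fit statistics."""

    components: CovarianceSet
    blue: np.ndarray                      # fixed effects, stacked per trait
    blup_g: np.ndarray | None             # n_progeny x traits deviations g
    blup_i: np.ndarray | None             # n_cells x traits interaction effects
    pev_g: np.ndarray | None              # n_progeny x traits
    fixed_mean: np.ndarray                # per-trait mean of the fitted fixed part
    logL: float
    n_varparams: int
    converged: bool
    n_iter: int
    progeny_ids: list[str] = field(default_factory=list)
    trait_names: tuple[str, ...] = ()
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def deviance(self) -> float:
        return -2.0 * self.logL

    @property
    def u_plus_g(self) -> np.ndarray | None:
        """Breeding values u+g: per-trait fitted mean plus progeny deviation."""
        if self.blup_g is None:
            return None
        return self.fixed_mean[None, :] + self.blup_g


# ---------------------------------------------------------------------------
# Precomputed design cross-products, grouped by missing-data pattern
# ---------------------------------------------------------------------------

class _MMEWork:
    """Cross-products of the stacked design, grouped by the per-plot pattern
    of observed traits, so that R-inverse weighting reduces to scalar
    combinations of precomputed sparse matrices."""

    def __init__(self, design: DesignSet, allow_missing: bool = False):
        if design.missing_mask.any() and not allow_missing:
            raise ValueError("fit on a design built with keep_missing=True; "
                             "rebuild with keep_missing=False (rows dropped)")
        self.design = design
        t = design.n_traits
        X, Z, W = design.X, design.Z, design.W
        self.p_X = X.shape[1]
        self.q = design.n_progeny if Z is not None else 0
        self.m = design.n_cells if W is not None else 0
        blocks = [X] + [b for b in (Z, W) if b is not None]
        T = sp.hstack(blocks, format="csr")
        self.T = T
        self.P = T.shape[1]
        self.g_off = self.p_X
        self.i_off = self.p_X + (self.q * t if Z is not None else 0)
        self.has_g = Z is not None
        self.has_i = W is not None
        self.N = design.n_obs

        # design row index for (trait k, plot p); -1 when unobserved
        row_of = np.full((t, design.n_plots), -1, dtype=np.int64)
        rows = np.arange(design.n_obs)
        row_of[design.trait_of_row, design.plot_of_row] = rows
        # group plots by observed-trait pattern
        obs = row_of >= 0
        pat_key = (obs.astype(np.int64)
                   * (1 << np.arange(t))[:, None]).sum(axis=0)
        self.patterns = []
        y = design.y
        for key in np.unique(pat_key):
            if key == 0:
                continue
            plots = np.flatnonzero(pat_key == key)
            traits = tuple(k for k in range(t) if key >> k & 1)
            rows_by_trait = {k: row_of[k, plots] for k in traits}
            Trows = {k: T[rows_by_trait[k]].tocsr() for k in traits}
            K, Ty, yy = {}, {}, {}
            for ia, a in enumerate(traits):
                for b in traits[ia:]:
                    Kab = (Trows[a].T @ Trows[b]).tocoo()
                    K[(a, b)] = (Kab.row, Kab.col, Kab.data)
                    Ty[(a, b)] = Trows[a].T @ y[rows_by_trait[b]]
                    if a != b:
                        Ty[(b, a)] = Trows[b].T @ y[rows_by_trait[a]]
                    yy[(a, b)] = float(y[rows_by_trait[a]]
                                       @ y[rows_by_trait[b]])
            self.patterns.append({
                "traits": traits, "plots": plots, "n": len(plots),
                "rows_by_trait": rows_by_trait, "Trows": Trows,
                "K": K, "Ty": Ty, "yy": yy,
            })
        # plots observed for each trait pair (for the Sigma_e EM update)
        self.n_pair = np.zeros((t, t))
        for pat in self.patterns:
            for a in pat["traits"]:
                for b in pat["traits"]:
                    self.n_pair[a, b] += pat["n"]


def _sub_inverse(sigma_e: np.ndarray, traits: tuple[int, ...]) -> np.ndarray:
    sub = sigma_e[np.ix_(traits, traits)]
    return np.linalg.inv(sub), float(np.linalg.slogdet(sub)[1])


def _assemble_mme(work: _MMEWork, comps: CovarianceSet
                  ) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Dense MME coefficient matrix, right-hand side and the scalar pieces
    (y'R^-1 y, log|R|, log|G|) at the given components."""
    t = comps.n_traits
    P = work.P
    M = np.zeros((P, P))
    rhs = np.zeros(P)
    yRy = 0.0
    logdetR = 0.0
    for pat in work.patterns:
        traits = pat["traits"]
        local = {a: i for i, a in enumerate(traits)}
        Rinv, ld = _sub_inverse(comps.sigma_e, traits)
        logdetR += pat["n"] * ld
        for ia, a in enumerate(traits):
            for b in traits[ia:]:
                c = Rinv[local[a], local[b]]
                r, cc, v = pat["K"][(a, b)]
                np.add.at(M, (r, cc), c * v)
                if a != b:
                    np.add.at(M, (cc, r), c * v)
                    rhs += c * (pat["Ty"][(a, b)] + pat["Ty"][(b, a)])
                    yRy += 2.0 * c * pat["yy"][(a, b)]
                else:
                    rhs += c * pat["Ty"][(a, b)]
                    yRy += c * pat["yy"][(a, b)]

    logdetG = 0.0
    ar = np.arange
    if work.has_g:
        ginv = np.linalg.inv(comps.sigma_g)
        logdetG += work.q * float(np.linalg.slogdet(comps.sigma_g)[1])
        for s in range(t):
            for u in range(t):
                M[work.g_off + s * work.q + ar(work.q),
                  work.g_off + u * work.q + ar(work.q)] += ginv[s, u]
    if work.has_i:
        iinv = np.linalg.inv(comps.sigma_int)
        logdetG += work.m * float(np.linalg.slogdet(comps.sigma_int)[1])
        for s in range(t):
            for u in range(t):
                M[work.i_off + s * work.m + ar(work.m),
                  work.i_off + u * work.m + ar(work.m)] += iinv[s, u]
    return M, rhs, yRy, logdetR, logdetG


def marginal_deviance(work: _MMEWork, comps: CovarianceSet,
                      beta: np.ndarray) -> float:
    """-2 log N(y; X beta, V) with V = Z(Sg(x)I)Z' + W(Si(x)I)W' + R,
    i.e. the Gaussian deviance conditional on the fixed effects and the
    variance components, with the random effects integrated out.  Computed
    through the MME blocks (Woodbury), never by forming V."""
    M, rhs, yRy, logdetR, logdetG = _assemble_mme(work, comps)
    p = work.p_X
    b = np.asarray(beta, float)
    rRr = yRy - 2.0 * float(b @ rhs[:p]) + float(b @ M[:p, :p] @ b)
    if M.shape[0] > p:
        Mr = M[p:, p:]
        z = rhs[p:] - M[p:, :p] @ b
        cf = la.cho_factor(Mr, lower=True, check_finite=False)
        logdetMr = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        quad = rRr - float(z @ la.cho_solve(cf, z, check_finite=False))
        logdetV = logdetR + logdetG + logdetMr
    else:
        quad, logdetV = rRr, logdetR
    return work.N * _LOG2PI + logdetV + quad


class _MMEEval:
    """One solve of the mixed-model equations at fixed components."""

    def __init__(self, work: _MMEWork, comps: CovarianceSet,
                 want_inverse: bool = False):
        P = work.P
        M, rhs, yRy, logdetR, logdetG = _assemble_mme(work, comps)
        try:
            cf = la.cho_factor(M, lower=True, check_finite=False)
        except la.LinAlgError:
            cond = np.linalg.cond(M)
            raise NumericalError(
                f"singular MME coefficient matrix (cond={cond:.3g}); "
                "check for zero residual variance or confounded factors")
        self.sol = la.cho_solve(cf, rhs, check_finite=False)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = yRy - float(rhs @ self.sol)
        self.logL = -0.5 * ((work.N - work.p_X) * _LOG2PI
                            + logdetR + logdetG + logdetM + yPy)
        self.C = (la.cho_solve(cf, np.eye(P), check_finite=False)
                  if want_inverse else None)
        self.work = work
        self.comps = comps

    # -- effect extraction -----------------------------------------------
    def blue(self) -> np.ndarray:
        return self.sol[:self.work.p_X]

    def blup_g(self) -> np.ndarray | None:
        w = self.work
        if not w.has_g:
            return None
        t = self.comps.n_traits
        return self.sol[w.g_off:w.g_off + w.q * t].reshape(t, w.q).T

    def blup_i(self) -> np.ndarray | None:
        w = self.work
        if not w.has_i:
            return None
        t = self.comps.n_traits
        return self.sol[w.i_off:w.i_off + w.m * t].reshape(t, w.m).T

    def pev_g(self) -> np.ndarray | None:
        w = self.work
        if not w.has_g or self.C is None:
            return None
        t = self.comps.n_traits
        d = np.diag(self.C)
        pev = np.column_stack(
            [d[w.g_off + s * w.q: w.g_off + (s + 1) * w.q]
             for s in range(t)])
        # PEV cannot exceed the prior variance of the effect
        return np.clip(pev, 0.0, np.diag(self.comps.sigma_g)[None, :])

    def fixed_mean(self) -> np.ndarray:
        """Per-trait mean of the fitted fixed part over that trait's rows."""
        w = self.work
        fitted = w.design.X @ self.blue()
        t = self.comps.n_traits
        return np.array([fitted[w.design.trait_of_row == k].mean()
                         for k in range(t)])

    def _cond_block_sum(self, off: int, n: int) -> np.ndarray:
        """Sum over levels of the t x t conditional-covariance blocks."""
        t = self.comps.n_traits
        S = np.empty((t, t))
        ar = np.arange(n)
        for s in range(t):
            for u in range(s, t):
                S[s, u] = S[u, s] = float(
                    self.C[off + s * n + ar, off + u * n + ar].sum())
        return S

    def em_update(self) -> CovarianceSet:
        """One EM-REML step: conditional expectations of effect outer
        products given y at the current components."""
        w, t = self.work, self.comps.n_traits
        new_g = new_i = None
        if w.has_g:
            G = self.blup_g()
            new_g = (G.T @ G + self._cond_block_sum(w.g_off, w.q)) / w.q
        if w.has_i:
            I_ = self.blup_i()
            new_i = (I_.T @ I_ + self._cond_block_sum(w.i_off, w.m)) / w.m

        ehat = w.design.y - w.T @ self.sol
        S = np.zeros((t, t))
        for pat in self.patterns_iter():
            traits = pat["traits"]
            for ia, a in enumerate(traits):
                for b in traits[ia:]:
                    ra = pat["rows_by_trait"][a]
                    rb = pat["rows_by_trait"][b]
                    cross = float(ehat[ra] @ ehat[rb])
                    r, cc, v = pat["K"][(a, b)]
                    corr = float((self.C[r, cc] * v).sum())
                    S[a, b] += cross + corr
                    if a != b:
                        S[b, a] += cross + corr
        with np.errstate(invalid="ignore", divide="ignore"):
            new_e = np.where(w.n_pair > 0, S / w.n_pair, self.comps.sigma_e)
        return CovarianceSet(new_g, new_i, new_e)

    def patterns_iter(self):
        return self.work.patterns


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def solve_mme(design: DesignSet, components: CovarianceSet) -> FreqFit:
    """BLUE/BLUP/PEV at fixed variance components (Henderson's equations)."""
    if float(np.linalg.det(components.sigma_e)) <= 0:
        raise NumericalError("sigma_e must be positive definite "
                             "(zero residual variance is degenerate)")
    work = _MMEWork(design)
    ev = _MMEEval(work, components, want_inverse=True)
    return FreqFit(
        components=components, blue=ev.blue(), blup_g=ev.blup_g(),
        blup_i=ev.blup_i(), pev_g=ev.pev_g(), fixed_mean=ev.fixed_mean(),
        logL=ev.logL, n_varparams=components.n_varparams(),
        converged=True, n_iter=0, progeny_ids=design.progeny_ids,
        trait_names=design.trait_names,
    )


def reml_loglik(design: DesignSet, components: CovarianceSet) -> float:
    """Restricted log-likelihood at the given components (constant
    convention as in the module docstring)."""
    return _MMEEval(_MMEWork(design), components).logL


def default_init(design: DesignSet) -> CovarianceSet:
    """Trait-wise phenotypic covariance split equally among the included
    components (pairwise-complete sample moments)."""
    t = design.n_traits
    cols = np.full((design.n_plots, t), np.nan)
    cols[design.plot_of_row, design.trait_of_row] = design.y
    import pandas as pd
    phen = pd.DataFrame(cols).cov().to_numpy()
    phen = nearest_psd(phen, eps=1e-8)
    n_terms = 1 + (design.Z is not None) + (design.W is not None)
    part = phen / n_terms
    return CovarianceSet(
        part if design.Z is not None else None,
        part if design.W is not None else None,
        part,
    )


def _flatten(comps: CovarianceSet) -> np.ndarray:
    return np.concatenate([m.ravel() for m in
                           (comps.sigma_g, comps.sigma_int, comps.sigma_e)
                           if m is not None])


def _unflatten(vec: np.ndarray, like: CovarianceSet) -> CovarianceSet:
    t = like.n_traits
    out, k = [], 0
    for m in (like.sigma_g, like.sigma_int, like.sigma_e):
        if m is None:
            out.append(None)
        else:
            out.append(vec[k:k + t * t].reshape(t, t))
            k += t * t
    return CovarianceSet(*out)


def _sanitize(comps: CovarianceSet, scale: float) -> CovarianceSet:
    """PSD-project each block; keep sigma_e strictly positive definite."""
    g = (None if comps.sigma_g is None
         else nearest_psd(comps.sigma_g, eps=1e-10))
    i = (None if comps.sigma_int is None
         else nearest_psd(comps.sigma_int, eps=1e-10))
    e = nearest_psd(comps.sigma_e, eps=1e-8)
    if np.linalg.eigvalsh(e).min() < 1e-10 * scale:
        e = e + 1e-10 * scale * np.eye(e.shape[0])
    return CovarianceSet(g, i, e)


def fit_reml(design: DesignSet, init: CovarianceSet | None = None,
             tol: float = 1e-9, max_iter: int = 5000,
             accelerate: bool = True, verbose: bool = False) -> FreqFit:
    """EM-REML estimation of the variance components, then effects.

    The EM iteration is monotone in the restricted log-likelihood; an
    Aitken-extrapolated candidate is attempted periodically and accepted
    only if it is PSD-valid and does not decrease the log-likelihood.
    Stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations (``converged`` flag set accordingly).
    """
    work = _MMEWork(design)
    comps = (init.copy() if init is not None else default_init(design))
    scale = float(np.trace(comps.sigma_e))
    comps = _sanitize(comps, scale)

    trace: list[float] = []
    prev_vecs: list[np.ndarray] = []
    ev = _MMEEval(work, comps, want_inverse=True)
    trace.append(ev.logL)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = _sanitize(ev.em_update(), scale)
        new_ev = _MMEEval(work, new, want_inverse=True)
        if new_ev.logL < trace[-1] - 1e-6 * (1 + abs(trace[-1])):
            warnings.warn("EM step decreased restricted logL by "
                          f"{trace[-1] - new_ev.logL:.3g}; numerical noise")
        prev_vecs.append(_flatten(new))
        prev_vecs = prev_vecs[-3:]

        if accelerate and len(prev_vecs) == 3 and it % 4 == 0:
            d1 = prev_vecs[1] - prev_vecs[0]
            d2 = prev_vecs[2] - prev_vecs[1]
            denom = float(d1 @ d1)
            if denom > 0:
                r = float(d1 @ d2) / denom
                if 0 < r < 0.999:
                    cand_vec = prev_vecs[2] + d2 * r / (1 - r)
                    cand = _sanitize(_unflatten(cand_vec, new), scale)
                    try:
                        cand_ev = _MMEEval(work, cand, want_inverse=True)
                        if cand_ev.logL >= new_ev.logL:
                            new, new_ev = cand, cand_ev
                            prev_vecs = [_flatten(new)]
                    except NumericalError:
                        pass

        rel = abs(new_ev.logL - trace[-1]) / (1.0 + abs(new_ev.logL))
        comps, ev = new, new_ev
        trace.append(ev.logL)
        if verbose and it % 50 == 0:
            print(f"  EM iter {it}: logL={ev.logL:.6f}")
        if rel < tol:
            converged = True
            break

    return FreqFit(
        components=comps, blue=ev.blue(), blup_g=ev.blup_g(),
        blup_i=ev.blup_i(), pev_g=ev.pev_g(), fixed_mean=ev.fixed_mean(),
        logL=ev.logL, n_varparams=comps.n_varparams(),
        converged=converged, n_iter=it, progeny_ids=design.progeny_ids,
        trait_names=design.trait_names, loglik_trace=trace,
    )


def aic_value(deviance: float, n_varparams: int) -> float:
    """AIC = deviance + 2p, with p the number of variance-covariance
    parameters (fixed effects excluded)."""
    if n_varparams < 0:
        raise ValueError("n_varparams must be >= 0")
    return deviance + 2.0 * n_varparams


def lrt(deviance_reduced: float, deviance_full: float,
        df: int = 1, tolerance: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio test statistic and chi-square p-value.

    lambda = deviance(reduced) - deviance(full); df defaults to 1 (the
    single-trait convention of dropping one variance component).  At
    lambda = 0 the p-value is 1 (no boundary-mixture correction applied).
    """
    lam = deviance_reduced - deviance_full
    if lam < -tolerance:
        warnings.warn(f"negative LRT statistic {lam:.3g}; "
                      "reduced model fits better than full (clamped to 0)")
    lam = max(lam, 0.0)
    p = 1.0 if lam == 0.0 else float(chi2.sf(lam, df))
    return lam, p
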