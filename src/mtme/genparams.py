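"""Derived genetic and non-genetic parameters.

From fitted variance components and effects this module derives, per trait:

* broad-sense heritability per plot (progeny-mean basis),
  h2 = sg2 / (sg2 + sint2/n + se2/(n r)) for n locations, r replicates;
* coefficient of determination of the interaction, c2_int = sint2/sphen2
  with sphen2 = sg2 + sint2 + se2;
* genotypic and residual coefficients of variation, CVg = sqrt(sg2)/mean,
  CVe = sqrt(se2)/mean (unitless ratios, not percent);
* selection accuracy from PEV, sqrt((sg2 - PEV)/sg2), and the posterior
  accuracy 1 - sd(g)/|g| used with MCMC breeding-value chains;

plus trait-by-trait genetic correlations, including the pairwise
sum-of-traits covariance trick used to recover genetic covariances from
three single-trait fits.  Correlations outside [-1, 1] (possible with the
sum trick) are returned unclipped and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reml import CovarianceSet


@dataclass
class GeneticParameters:
    """Per-trait derived parameters plus the genetic correlation matrix."""

    trait_names: tuple[str, ...]
    h2_prog: np.ndarray
    c2_int: np.ndarray
    cv_g: np.ndarray
    cv_e: np.ndarray
    sigma_phen: np.ndarray
    gen_corr: np.ndarray | None = None
    corr_flags: np.ndarray | None = None          # True where |rho| > 1
    accuracy: np.ndarray | None = None
    messages: list[str] = field(default_factory=list)


def derive_genetic_parameters(components: CovarianceSet,
                              grand_means: np.ndarray,
                              n_locations: int, n_reps: int,
                              trait_names: tuple[str, ...] = ()
                              ) -> GeneticParameters:
    """Heritability, interaction determination, CVs and genetic correlations
    from a fitted covariance set."""
    if n_locations < 1 or n_reps < 1:
        raise ValueError("n_locations and n_reps must be >= 1")
    if components.sigma_g is None or components.sigma_int is None:
        raise ValueError("full model components (g and interaction) required")
    sg = np.diag(components.sigma_g).astype(float)
    si = np.diag(components.sigma_int).astype(float)
    se = np.diag(components.sigma_e).astype(float)
    if (sg < 0).any() or (si < 0).any() or (se < 0).any():
        raise ValueError("negative variance component")
    means = np.asarray(grand_means, float).reshape(sg.shape)
    if (means <= 0).any():
        raise ValueError("grand means must be positive for CV computation")

    denom = sg + si / n_locations + se / (n_locations * n_reps)
    if (denom == 0).any():
        raise ValueError("zero phenotypic variance of progeny means")
    sphen = sg + si + se
    h2 = sg / denom
    c2 = si / sphen
    cvg = np.sqrt(sg) / means
    cve = np.sqrt(se) / means

    corr = flags = None
    if components.sigma_g.shape[0] > 1:
        corr, flags = gen_correlation(components.sigma_g)
    t = len(sg)
    names = tuple(trait_names) if trait_names else tuple(
        f"trait{i + 1}" for i in range(t))
    return GeneticParameters(
        trait_names=names, h2_prog=h2, c2_int=c2, cv_g=cvg, cv_e=cve,
        sigma_phen=sphen, gen_corr=corr, corr_flags=flags)


def accuracy_pev(sigma_g_diag: float | np.ndarray,
                 pev: float | np.ndarray) -> np.ndarray:
    """Selection accuracy sqrt((sg2 - PEV)/sg2) per progeny.

    Values of PEV above sg2 (numerical) are clamped to accuracy 0 with a
    warning.  The mean across progeny is the trait's reported accuracy.
    """
    sg = np.asarray(sigma_g_diag, float)
    pev = np.asarray(pev, float)
    if (sg <= 0).any():
        raise ValueError("sigma_g diagonal must be positive")
    ratio = (sg - pev) / sg
    if (ratio < 0).any():
        warnings.warn("PEV exceeded sigma_g for some progeny; "
                      "accuracy clamped to 0")
        ratio = np.clip(ratio, 0.0, None)
    return np.sqrt(np.clip(ratio, 0.0, 1.0))


def accuracy_posterior(g_mean: np.ndarray, g_sd: np.ndarray,
                       epsilon: float | None = None
                       ) -> tuple[np.ndarray, float, int]:
    """Posterior per-progeny accuracy 1 - sd(g)/|g|, truncated to [0, 1].

    Progeny with |posterior mean| below ``epsilon`` (default 1e-6 times the
    sd of the means) are excluded from the reported mean accuracy; the
    exclusion count is returned.
    """
    mu = np.asarray(g_mean, float)
    sd = np.asarray(g_sd, float)
    if epsilon is None:
        epsilon = 1e-6 * max(float(np.std(mu)), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = 1.0 - sd / np.abs(mu)
    acc = np.clip(acc, 0.0, 1.0)
    keep = np.abs(mu) >= epsilon
    n_excluded = int((~keep).sum())
    mean_acc = float(acc[keep].mean()) if keep.any() else float("nan")
    return acc, mean_acc, n_excluded


def cov_sum_trick(var_i: float, var_j: float, var_sum: float) -> float:
    """Genetic covariance from three single-trait genetic variances:
    cov = (var(i+j) - var(i) - var(j)) / 2."""
    return 0.5 * (var_sum - var_i - var_j)


def gen_correlation(cov_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix from a genetic covariance matrix.

    Off-diagonal values with |rho| > 1 (possible when the covariance comes
    from the single-trait sum trick rather than a joint PSD fit) are
    returned unclipped with their flag set.
    """
    cov = np.atleast_2d(np.asarray(cov_g, float))
    d = np.diag(cov)
    if (d <= 0).any():
        raise ValueError("zero or negative genetic variance on the diagonal")
    sd = np.sqrt(d)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    flags = np.abs(corr) > 1.0 + 1e-12
    return corr, flags
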