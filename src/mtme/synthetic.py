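"""Synthetic balanced multi-environment progeny trials with known truth.

The generator emulates a randomized-complete-block soybean progeny trial:
``n_progeny`` families evaluated in ``n_locations`` sites with ``n_blocks``
replicates per site, and correlated traits generated under the standard
multi-trait multi-environment (MTME) mixed model

    y = fixed(location, block-within-location) + g + i + e,

with progeny effect rows g ~ N(0, sigma_g), progeny-by-location interaction
rows i ~ N(0, sigma_int) and plot residual rows e ~ N(0, sigma_e), all
independent across progeny / progeny-location cells / plots.

``soybean_trial_params`` returns the preset matching the soybean study scale:
203 F2:4 progeny from 3 populations, 2 locations, 3 blocks, traits DM
(days to maturity), SW (100-seed weight, g) and SY (seed yield per plot, g),
with the published MTME genetic variances and genetic correlations (in
particular the near-unity DM-SY genetic correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_io import ID_COLUMNS, PhenotypeTable


class ParameterError(ValueError):
    """Invalid simulation parameters (e.g. a non-PSD covariance matrix)."""


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.shape[0] != mat.shape[1]:
        raise ParameterError(f"{name} is not square: shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-12 * (1 + np.abs(mat).max())):
        raise ParameterError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, w.max()):
        raise ParameterError(
            f"{name} is not positive semi-definite "
            f"(smallest eigenvalue {w.min():.6g}): {mat.tolist()}")
    return mat


@dataclass
class TrialParams:
    """Ground-truth parameters of a simulated trial.

    Covariance matrices are trait-by-trait (1x1 in the single-trait case);
    fixed effects are per-trait.  ``location_effects`` has one row per
    location, ``block_effects`` one row per (location, block) pair in
    location-major order; both are in trait units.
    """

    n_progeny: int
    n_locations: int
    n_blocks: int
    trait_names: tuple[str, ...]
    grand_means: np.ndarray
    sigma_g: np.ndarray
    sigma_int: np.ndarray
    sigma_e: np.ndarray
    location_effects: np.ndarray | None = None
    block_effects: np.ndarray | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_progeny, self.n_locations, self.n_blocks) < 1:
            raise ParameterError("counts must be >= 1")
        t = len(self.trait_names)
        self.trait_names = tuple(self.trait_names)
        self.grand_means = np.asarray(self.grand_means, dtype=float).reshape(t)
        self.sigma_g = _check_psd(self.sigma_g, "sigma_g")
        self.sigma_int = _check_psd(self.sigma_int, "sigma_int")
        self.sigma_e = _check_psd(self.sigma_e, "sigma_e")
        for m in (self.sigma_g, self.sigma_int, self.sigma_e):
            if m.shape != (t, t):
                raise ParameterError(
                    f"covariance dimension {m.shape} does not match "
                    f"{t} traits")
        if self.location_effects is None:
            self.location_effects = np.zeros((self.n_locations, t))
        self.location_effects = np.asarray(
            self.location_effects, dtype=float).reshape(self.n_locations, t)
        if self.block_effects is None:
            self.block_effects = np.zeros(
                (self.n_locations * self.n_blocks, t))
        self.block_effects = np.asarray(
            self.block_effects, dtype=float).reshape(
                self.n_locations * self.n_blocks, t)
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ParameterError("missing_rate must be in [0, 1]")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_plots(self) -> int:
        return self.n_progeny * self.n_locations * self.n_blocks


@dataclass
class TruthRecord:
    """Simulation truth: the drawn progeny and interaction effects."""

    progeny_effects: np.ndarray     # n_progeny x traits
    gxe_effects: np.ndarray         # (n_progeny * n_locations) x traits
    params_used: TrialParams
    seed: int
    progeny_ids: list[str] = field(default_factory=list)
    cell_ids: list[tuple[str, str]] = field(default_factory=list)


def _mvn_rows(rng: np.random.Generator, n: int, cov: np.ndarray) -> np.ndarray:
    """n i.i.d. zero-mean rows with covariance ``cov`` (PSD-safe)."""
    t = cov.shape[0]
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    return rng.standard_normal((n, t)) @ root.T


def simulate_trial(params: TrialParams,
                   seed: int) -> tuple[PhenotypeTable, TruthRecord]:
    """Simulate one balanced trial; deterministic given ``seed``.

    Draw order is fixed (progeny effects, then interaction effects, then
    plot residuals, then the missing-cell mask) so that seeds are portable
    across parameter settings with the same dimensions.
    """
    rng = np.random.default_rng(seed)
    q, L, B, t = (params.n_progeny, params.n_locations, params.n_blocks,
                  params.n_traits)

    width = len(str(q))
    progeny_ids = [f"P{j + 1:0{width}d}" for j in range(q)]
    loc_ids = [f"L{l + 1}" for l in range(L)]
    blk_ids = [f"B{b + 1}" for b in range(B)]
    pops = [f"Pop{j % 3 + 1}" for j in range(q)]

    g = _mvn_rows(rng, q, params.sigma_g)
    i = _mvn_rows(rng, q * L, params.sigma_int)      # progeny-major per location
    e = _mvn_rows(rng, q * L * B, params.sigma_e)

    rows = []
    vals = np.empty((q * L * B, t))
    r = 0
    for l in range(L):
        for b in range(B):
            for j in range(q):
                y = (params.grand_means
                     + params.location_effects[l]
                     + params.block_effects[l * B + b]
                     + g[j] + i[l * q + j] + e[r])
                rows.append((progeny_ids[j], pops[j], loc_ids[l], blk_ids[b]))
                vals[r] = y
                r += 1

    if params.missing_rate > 0:
        mask = rng.random((q * L * B, t)) < params.missing_rate
        vals[mask] = np.nan

    df = pd.DataFrame(rows, columns=list(ID_COLUMNS))
    for k, name in enumerate(params.trait_names):
        df[name] = vals[:, k]
    table = PhenotypeTable(df, params.trait_names)

    cell_ids = [(loc_ids[l], progeny_ids[j])
                for l in range(L) for j in range(q)]
    truth = TruthRecord(progeny_effects=g, gxe_effects=i, params_used=params,
                        seed=seed, progeny_ids=progeny_ids, cell_ids=cell_ids)
    return table, truth


def _corr_to_cov(diag: np.ndarray, corr: np.ndarray) -> np.ndarray:
    sd = np.sqrt(diag)
    return corr * np.outer(sd, sd)


def soybean_trial_params(n_progeny: int = 203,
                      interaction_corr: float = 0.3,
                      residual_corr: float = 0.3,
                      missing_rate: float = 0.0) -> TrialParams:
    """Preset on the scale of the soybean MTME study.

    Genetic (progeny) variances and correlations are the published MTME
    estimates; interaction and residual variances likewise.  Cross-trait
    interaction and residual correlations are not published, so a uniform
    moderate default (0.3) is used and is configurable.  Fixed effects:
    location 2 gets +5% of each grand mean; blocks get small symmetric
    offsets (-1%, 0, +1% of the mean) so the fixed part of the model is
    exercised without dominating the variance.
    """
    traits = ("DM", "SW", "SY")
    means = np.array([143.45, 18.43, 20.82])
    g_diag = np.array([130.947, 1.8084, 10.4882])
    g_corr = np.array([
        [1.0, -0.1107, 0.9718],
        [-0.1107, 1.0, -0.0217],
        [0.9718, -0.0217, 1.0],
    ])
    int_diag = np.array([31.6741, 0.6228, 8.2995])
    e_diag = np.array([56.5234, 1.5006, 36.4419])

    def uniform_corr(rho: float) -> np.ndarray:
        c = np.full((3, 3), rho)
        np.fill_diagonal(c, 1.0)
        return c

    loc_eff = np.vstack([np.zeros(3), 0.05 * means])
    blk_frac = np.array([-0.01, 0.0, 0.01])
    blk_eff = np.vstack([f * means for _ in range(2) for f in blk_frac])

    return TrialParams(
        n_progeny=n_progeny, n_locations=2, n_blocks=3,
        trait_names=traits, grand_means=means,
        sigma_g=_corr_to_cov(g_diag, g_corr),
        sigma_int=_corr_to_cov(int_diag, uniform_corr(interaction_corr)),
        sigma_e=_corr_to_cov(e_diag, uniform_corr(residual_corr)),
        location_effects=loc_eff, block_effects=blk_eff,
        missing_rate=missing_rate,
    )
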