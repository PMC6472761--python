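"""Model specification and incidence-matrix construction.

Translates a :class:`~mtme.trial_io.PhenotypeTable` plus a model choice into
the response vector and incidence matrices of the mixed model

    y = X b + Z g + W i + e

with fixed effects b (overall mean + location + block-within-location under
reference-level coding), random progeny effects g and random
progeny-by-location interaction effects i.  Multi-trait designs stack the
traits trait-major: all rows of trait 1, then trait 2, ...  Random-effect
columns follow the same trait-major order, so a Kronecker covariance
``Sigma (x) I`` indexes consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .trial_io import PhenotypeTable


class SpecError(ValueError):
    """Model specification inconsistent with the table."""


@dataclass
class ModelSpec:
    """Which traits and which random terms enter the model.

    ``include_progeny`` / ``include_interaction`` allow the reduced models
    used in likelihood-ratio and information-criterion comparisons.
    """

    traits: tuple[str, ...]
    include_progeny: bool = True
    include_interaction: bool = True

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        if len(self.traits) < 1:
            raise SpecError("at least one trait required")

    @property
    def multitrait(self) -> bool:
        return len(self.traits) > 1


@dataclass
class DesignSet:
    """Response and incidence matrices for one model fit.

    Rows are trait-major; ``obs_index`` maps every row to its
    (progeny, location, block, trait).  ``Z`` has one column per progeny
    per trait (trait-major), ``W`` one column per location-progeny cell per
    trait.  Missing cells are dropped unless the design was built with
    ``keep_missing=True``, in which case they remain as NaN rows flagged in
    ``missing_mask`` (used by the Gibbs sampler's data augmentation).
    """

    y: np.ndarray
    X: sp.csr_matrix
    Z: sp.csr_matrix | None
    W: sp.csr_matrix | None
    obs_index: pd.DataFrame
    missing_mask: np.ndarray
    trait_names: tuple[str, ...]
    progeny_ids: list[str]
    location_ids: list[str]
    cell_ids: list[tuple[str, str]]          # (location, progeny), location-major
    plot_of_row: np.ndarray = field(repr=False, default=None)
    trait_of_row: np.ndarray = field(repr=False, default=None)
    n_plots: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_progeny(self) -> int:
        return len(self.progeny_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _fixed_block(df: pd.DataFrame, locations: list[str],
                 blocks_by_loc: dict[str, list[str]]) -> np.ndarray:
    """Reference-level fixed-effect design for one trait's rows.

    Columns: intercept, location contrasts (all but first), then
    block-within-location contrasts (all but first block of each location).
    """
    n = len(df)
    cols = [np.ones(n)]
    for loc in locations[1:]:
        cols.append((df["location"] == loc).to_numpy(float))
    for loc in locations:
        for blk in blocks_by_loc[loc][1:]:
            cols.append(((df["location"] == loc)
                         & (df["block"] == blk)).to_numpy(float))
    return np.column_stack(cols)


def build_design(table: PhenotypeTable, spec: ModelSpec,
                 keep_missing: bool = False) -> DesignSet:
    """Build the stacked response and incidence matrices for ``spec``.

    Row order within each trait block follows the table's row order; traits
    are stacked trait-major.  Rows whose trait value is missing are dropped
    (observed-data likelihood) unless ``keep_missing``.
    """
    for t in spec.traits:
        if t not in table.trait_names:
            raise SpecError(f"trait {t!r} not present in table")

    df = table.data
    progeny_ids = sorted(df["progeny"].unique())
    locations = sorted(df["location"].unique())
    blocks_by_loc = {
        loc: sorted(df.loc[df["location"] == loc, "block"].unique())
        for loc in locations}
    cell_ids = [(loc, p) for loc in locations for p in progeny_ids]

    p_idx = {p: j for j, p in enumerate(progeny_ids)}
    c_idx = {c: j for j, c in enumerate(cell_ids)}
    n_plots = len(df)
    q, m, t = len(progeny_ids), len(cell_ids), len(spec.traits)

    X0 = _fixed_block(df, locations, blocks_by_loc)
    zrow = df["progeny"].map(p_idx).to_numpy()
    wrow = np.array([c_idx[(l, p)]
                     for l, p in zip(df["location"], df["progeny"])])

    ys, keep_rows, obs_rows = [], [], []
    for k, trait in enumerate(spec.traits):
        v = df[trait].to_numpy(float)
        keep = np.ones(n_plots, bool) if keep_missing else ~np.isnan(v)
        ys.append(v[keep])
        keep_rows.append(keep)
        sub = df.loc[keep, ["progeny", "location", "block"]].copy()
        sub["trait"] = trait
        obs_rows.append(sub)

    y = np.concatenate(ys)
    obs_index = pd.concat(obs_rows, ignore_index=True)
    missing_mask = np.isnan(y)

    Xb, Zb, Wb = [], [], []
    plot_of_row, trait_of_row = [], []
    ones_t = None
    for k in range(t):
        keep = keep_rows[k]
        nk = int(keep.sum())
        Xb.append(X0[keep])
        rows = np.arange(nk)
        ones_t = np.ones(nk)
        Zb.append(sp.csr_matrix((ones_t, (rows, zrow[keep])), shape=(nk, q)))
        Wb.append(sp.csr_matrix((ones_t, (rows, wrow[keep])), shape=(nk, m)))
        plot_of_row.append(np.flatnonzero(keep))
        trait_of_row.append(np.full(nk, k))

    X = sp.csr_matrix(sp.block_diag([sp.csr_matrix(b) for b in Xb]))
    Z = sp.csr_matrix(sp.block_diag(Zb)) if spec.include_progeny else None
    W = sp.csr_matrix(sp.block_diag(Wb)) if spec.include_interaction else None

    return DesignSet(
        y=y, X=X, Z=Z, W=W, obs_index=obs_index,
        missing_mask=missing_mask, trait_names=spec.traits,
        progeny_ids=progeny_ids, location_ids=locations, cell_ids=cell_ids,
        plot_of_row=np.concatenate(plot_of_row),
        trait_of_row=np.concatenate(trait_of_row),
        n_plots=n_plots,
    )


def drop_masked_rows(design: DesignSet) -> DesignSet:
    """Observed-rows view of a design built with ``keep_missing=True``."""
    if not design.missing_mask.any():
        return design
    keep = ~design.missing_mask
    take = lambda m: None if m is None else m[keep].tocsr()
    return DesignSet(
        y=design.y[keep], X=design.X[keep].tocsr(), Z=take(design.Z),
        W=take(design.W), obs_index=design.obs_index.loc[keep].reset_index(drop=True),
        missing_mask=np.zeros(int(keep.sum()), bool),
        trait_names=design.trait_names, progeny_ids=design.progeny_ids,
        location_ids=design.location_ids, cell_ids=design.cell_ids,
        plot_of_row=design.plot_of_row[keep],
        trait_of_row=design.trait_of_row[keep], n_plots=design.n_plots,
    )


def make_sum_trait(table: PhenotypeTable, trait_i: str,
                   trait_j: str) -> PhenotypeTable:
    """Add the plot-wise sum trait ``sum(i,j)`` used by the pairwise
    sum-of-traits genetic-covariance trick.

    A plot missing either component is missing in the sum.
    """
    if trait_i == trait_j:
        raise ValueError("sum trait requires two distinct traits")
    for t in (trait_i, trait_j):
        if t not in table.trait_names:
            raise SpecError(f"trait {t!r} not present in table")
    name = f"sum({trait_i},{trait_j})"
    df = table.data.copy()
    df[name] = df[trait_i] + df[trait_j]
    return PhenotypeTable(df, table.trait_names + (name,))
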