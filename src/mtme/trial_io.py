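"""Reading, validation and writing of plot-level progeny-trial tables.

A trial table is long-format: one row per plot, identified by
(progeny, location, block-within-location), with one numeric column per
trait.  Files are delimited text (comma or tab, auto-detected), UTF-8,
header row mandatory, ``.`` decimal separator, ``NA`` or empty cell =
missing.  Identifiers are opaque strings; no numeric ordering is assumed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COLUMNS = ("progeny", "population", "location", "block")
NA_VALUES = ["NA", "na", "NaN", ""]


class SchemaError(ValueError):
    """A declared column is absent from the file."""


class ParseError(ValueError):
    """A trait cell could not be interpreted as a number."""


class ValidationError(ValueError):
    """The table violates a structural invariant (e.g. duplicate plots)."""


@dataclass
class PhenotypeTable:
    """Plot-level records of a multi-environment progeny trial.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``progeny, population, location, block`` (strings) followed
        by one float column per trait; NaN marks a missing trait value.
    trait_names : tuple of str
        Trait columns, in order.  Units are trait-specific (e.g. days for
        maturity, grams for seed weight and yield).
    """

    data: pd.DataFrame
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.trait_names = tuple(self.trait_names)
        if len(self.trait_names) == 0:
            raise ValueError("at least one trait column is required")
        missing = [t for t in self.trait_names if t not in self.data.columns]
        if missing:
            raise ValueError(f"trait columns absent from data: {missing}")
        for c in ID_COLUMNS:
            if c not in self.data.columns:
                raise ValueError(f"identifier column {c!r} absent from data")
        df = self.data.copy()
        for c in ID_COLUMNS:
            df[c] = df[c].astype(str)
        for t in self.trait_names:
            df[t] = pd.to_numeric(df[t], errors="raise").astype(float)
        self.data = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def progeny_ids(self) -> list[str]:
        return sorted(self.data["progeny"].unique())

    @property
    def locations(self) -> list[str]:
        return sorted(self.data["location"].unique())

    @property
    def n_progeny(self) -> int:
        return self.data["progeny"].nunique()

    @property
    def n_locations(self) -> int:
        return self.data["location"].nunique()

    def n_blocks_per_location(self) -> dict[str, int]:
        g = self.data.groupby("location")["block"].nunique()
        return g.to_dict()

    def subset_traits(self, traits: list[str]) -> "PhenotypeTable":
        keep = list(ID_COLUMNS) + list(traits)
        return PhenotypeTable(self.data[keep].copy(), tuple(traits))


@dataclass
class ValidationReport:
    n_progeny: int
    n_locations: int
    n_blocks_per_location: dict[str, int]
    n_missing_cells: int
    balance_flag: bool
    messages: list[str] = field(default_factory=list)


def _detect_sep(path: str) -> str:
    with io.open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_phenotypes(path: str, schema: dict | None = None) -> PhenotypeTable:
    """Read a delimited trial file into a :class:`PhenotypeTable`.

    ``schema`` maps the canonical column names to the file's column names:
    ``{"progeny": ..., "population": ..., "location": ..., "block": ...,
    "traits": {canonical_trait: file_column, ...}}``.  With ``schema=None``
    the identifier columns must carry their canonical names and every other
    column is taken as a trait.  Row order is preserved; empty cells and
    ``NA`` become missing markers.
    """
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      na_values=[], encoding="utf-8")
    raw.columns = [c.strip() for c in raw.columns]

    if schema is None:
        colmap = {c: c for c in ID_COLUMNS}
        traitmap = {c: c for c in raw.columns if c not in ID_COLUMNS}
    else:
        colmap = {c: schema.get(c, c) for c in ID_COLUMNS}
        traitmap = dict(schema.get("traits", {}))
        if not traitmap:
            used = set(colmap.values())
            traitmap = {c: c for c in raw.columns if c not in used}

    for canon, col in list(colmap.items()) + list(traitmap.items()):
        if col not in raw.columns:
            raise SchemaError(f"declared column {col!r} (for {canon!r}) "
                              f"not found in {path}")
    if not traitmap:
        raise SchemaError("no trait columns declared or detected")

    out = pd.DataFrame({canon: raw[col] for canon, col in colmap.items()})
    for canon, col in traitmap.items():
        cell = raw[col].str.strip()
        cell = cell.where(~cell.isin(NA_VALUES), other=np.nan)
        try:
            out[canon] = pd.to_numeric(cell, errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(cell, errors="coerce")
            rows = np.flatnonzero(bad.isna() & cell.notna())
            raise ParseError(
                f"non-numeric value in column {col!r}, file row "
                f"{rows[0] + 2} (1-based incl. header): {cell.iloc[rows[0]]!r}"
            ) from None
    return PhenotypeTable(out, tuple(traitmap))


def write_phenotypes(table: PhenotypeTable, path: str, sep: str = "\t") -> None:
    """Write a table back to delimited text; NaN cells are written as ``NA``."""
    table.data.to_csv(path, sep=sep, index=False, na_rep="NA",
                      encoding="utf-8")


def validate_table(table: PhenotypeTable) -> ValidationReport:
    """Structural validation of a trial table.

    ``balance_flag`` is true iff every progeny appears exactly once in every
    (location, block) cell.  Duplicate (progeny, location, block) plots are
    an error.
    """
    df = table.data
    if len(df) == 0:
        raise ValidationError("empty table")
    key = ["progeny", "location", "block"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        dups = df.loc[dup, key].drop_duplicates().values.tolist()
        raise ValidationError(f"duplicate (progeny, location, block) plots: {dups}")

    n_missing = int(df[list(table.trait_names)].isna().sum().sum())
    msgs: list[str] = []

    counts = df.groupby(["location", "block"])["progeny"].agg(["nunique", "size"])
    progeny = set(df["progeny"])
    balanced = True
    for (loc, blk), row in counts.iterrows():
        cell = set(df.loc[(df["location"] == loc) & (df["block"] == blk),
                          "progeny"])
        if cell != progeny:
            balanced = False
            msgs.append(f"cell (location={loc}, block={blk}) is missing "
                        f"{len(progeny - cell)} progeny")
    return ValidationReport(
        n_progeny=table.n_progeny,
        n_locations=table.n_locations,
        n_blocks_per_location=table.n_blocks_per_location(),
        n_missing_cells=n_missing,
        balance_flag=balanced,
        messages=msgs,
    )
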