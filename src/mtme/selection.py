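"""Progeny ranking, selection gain, between-method agreement and the
additive genetic index (AGI).

Selection gain follows the printed-table arithmetic of progeny trials:
the mean breeding value (u+g) of the selected set minus the overall mean,
also expressed as a percentage of the overall mean.  Agreement between two
methods combines the Spearman rank correlation of the full breeding-value
vectors (with a progeny-resampling bootstrap CI) and the chance-corrected
coincidence index CI = (A - C)/(M - C), C = b*M with b the selection
intensity; C may be non-integer and the index may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr


@dataclass
class Ranking:
    """Ordered progeny ids (best first) with their criterion values."""

    order: list[str]
    values: pd.Series
    selected: list[str]

    @property
    def m(self) -> int:
        return len(self.selected)


def rank_and_select(values: pd.Series | dict, m: int,
                    direction: str = "maximize") -> Ranking:
    """Stable ranking of progeny by value; ties broken by progeny id.

    ``values`` maps progeny id to the selection criterion (e.g. u+g).
    """
    s = pd.Series(values, dtype=float)
    if m > len(s):
        raise ValueError(f"cannot select {m} of {len(s)} progeny")
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    asc = direction == "minimize"
    ordered = s.sort_index().sort_values(ascending=asc, kind="stable")
    order = list(ordered.index)
    return Ranking(order=order, values=s, selected=order[:m])


def gain_stats(selected_values: np.ndarray,
               overall_mean: float) -> tuple[float, float]:
    """Absolute and percent selection gain.

    gain_abs = mean(selected u+g) - overall mean;
    gain_pct = 100 * gain_abs / overall mean.
    """
    v = np.asarray(selected_values, float)
    if v.size == 0:
        raise ValueError("empty selection")
    gain_abs = float(v.mean() - overall_mean)
    if overall_mean <= 0:
        raise ValueError("overall mean must be positive for percent gain")
    return gain_abs, 100.0 * gain_abs / overall_mean


@dataclass
class AgreementResult:
    spearman_rho: float
    boot_ci: tuple[float, float]
    coincidence: float
    n_coincident: int
    messages: list[str] = field(default_factory=list)


def rank_agreement(values_a: pd.Series | dict, values_b: pd.Series | dict,
                   m: int, b_intensity: float = 0.15,
                   n_boot: int = 1000, seed: int = 0) -> AgreementResult:
    """Spearman correlation (with percentile bootstrap CI over progeny
    resampling) and coincidence index between two selection criteria.

    Both inputs must cover the same progeny set.  The coincidence index is
    (A - C)/(M - C) with A the overlap of the two top-m sets and C = b*M
    the chance overlap; negative values (worse than chance) are reported
    unclipped.
    """
    a = pd.Series(values_a, dtype=float).sort_index()
    b = pd.Series(values_b, dtype=float).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("progeny sets of the two methods differ")
    if not 0.0 < b_intensity < 1.0:
        raise ValueError("b_intensity must be in (0, 1)")

    av, bv = a.to_numpy(), b.to_numpy()
    rho = float(spearmanr(av, bv).statistic)

    rng = np.random.default_rng(seed)
    n = len(av)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rankdata(av[idx[i]])
        rb = rankdata(bv[idx[i]])
        ra -= ra.mean()
        rb -= rb.mean()
        denom = np.sqrt((ra @ ra) * (rb @ rb))
        boots[i] = (ra @ rb) / denom if denom > 0 else 0.0
    ci = (float(np.percentile(boots, 2.5)),
          float(np.percentile(boots, 97.5)))

    sel_a = set(rank_and_select(a, m).selected)
    sel_b = set(rank_and_select(b, m).selected)
    A = len(sel_a & sel_b)
    C = b_intensity * m
    coincidence = (A - C) / (m - C)
    return AgreementResult(spearman_rho=rho, boot_ci=ci,
                           coincidence=float(coincidence), n_coincident=A)


def agi_scores(blups: pd.DataFrame, weights: dict | pd.Series,
               standardize: bool = True) -> tuple[pd.Series, Ranking]:
    """Additive genetic index for simultaneous multi-trait selection.

    ``blups`` is progeny x trait (u+g or g deviations); ``weights`` gives a
    positive weight per trait (conventionally the trait's genotypic
    coefficient of variation).  With ``standardize=True`` (default) each
    trait column is divided by its standard deviation across progeny before
    weighting, making the ranking invariant to trait units; with
    ``standardize=False`` the weights act on the raw breeding values.
    All traits must be oriented so that higher is better.
    """
    w = pd.Series(weights, dtype=float)
    missing = [t for t in blups.columns if t not in w.index]
    if missing:
        raise ValueError(f"weights missing for traits: {missing}")
    if (w[blups.columns] <= 0).any():
        raise ValueError("AGI weights must be positive")
    mat = blups.astype(float)
    if standardize:
        sd = mat.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant trait column cannot be standardized")
        mat = mat / sd
    agi = (mat * w[blups.columns]).sum(axis=1)
    ranking = rank_and_select(agi, m=len(agi))
    return agi, ranking
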