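"""Rank-difference consistency and correlation between two score sets.

Scores are ranked descending (highest score = rank 1, average ranks on
ties) within each set over the groups common to both; the absolute rank
difference per group maps cross-compartment consistency (small = consistent).
Association is quantified by Spearman's rank correlation (two-sided p; exact
permutation p for n ≤ 9) and a simple least-squares regression of one score
set on the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(slots=True)
class RankComparison:
    group_id: str
    rank_a: float
    rank_b: float
    abs_rank_diff: float


@dataclass(slots=True)
class AssociationResult:
    n: int
    spearman_r: float
    spearman_p: float
    spearman_significant_at_01: bool
    slope: float
    intercept: float
    r_squared: float
    regression_p: float
    regression_significant_at_005: bool


def _as_series(scores) -> pd.Series:
    if isinstance(scores, pd.DataFrame):
        return scores.set_index("group_id")["score"]
    if isinstance(scores, pd.Series):
        return scores
    if isinstance(scores, Mapping):
        return pd.Series(scores, dtype=float)
    raise TypeError("scores must be a score table, Series or mapping")


def _common(scores_a, scores_b) -> tuple[pd.Series, pd.Series]:
    a, b = _as_series(scores_a), _as_series(scores_b)
    common = sorted(set(a.index) & set(b.index))
    return a.loc[common], b.loc[common]


def rank_difference(scores_a, scores_b) -> list[RankComparison]:
    """Per-group absolute difference of descending ranks in two score sets."""
    a, b = _common(scores_a, scores_b)
    if len(a) < 2:
        raise ValueError("need at least 2 common groups to rank")
    rank_a = stats.rankdata(-a.to_numpy(), method="average")
    rank_b = stats.rankdata(-b.to_numpy(), method="average")
    return [
        RankComparison(gid, float(ra), float(rb), float(abs(ra - rb)))
        for gid, ra, rb in zip(a.index, rank_a, rank_b)
    ]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n ≤ 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = len(rx)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        r = float(np.mean(rx * (ryp - ryp.mean()) / ryp.std()))
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def associate(scores_a, scores_b) -> AssociationResult:
    """Spearman correlation plus simple linear regression of b on a.

    ``scores_a`` is the independent variable (e.g. surface-water scores) and
    ``scores_b`` the dependent one (e.g. groundwater scores); only groups in
    both sets are paired. Significance labels use p < 0.1 for the correlation
    and p < 0.05 for the regression slope; they annotate, never filter.
    """
    a, b = _common(scores_a, scores_b)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 common groups for association")
    x, y = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant score set: correlation undefined")

    rho, p = stats.spearmanr(x, y)
    if n <= 9:
        p = _exact_spearman_p(x, y, float(rho))
    reg = stats.linregress(x, y)
    return AssociationResult(
        n=n,
        spearman_r=float(rho),
        spearman_p=float(p),
        spearman_significant_at_01=bool(p < 0.1),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue ** 2),
        regression_p=float(reg.pvalue),
        regression_significant_at_005=bool(reg.pvalue < 0.05),
    )


def rank_difference_table(scores_a, scores_b) -> pd.DataFrame:
    comps = rank_difference(scores_a, scores_b)
    return pd.DataFrame(
        [(c.group_id, c.rank_a, c.rank_b, c.abs_rank_diff) for c in comps],
        columns=["group_id", "rank_a", "rank_b", "abs_rank_diff"],
    )
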