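"""Bootstrap uncertainty for contamination scores.

Sites are the score's atomic unit, so they are also the resampling unit: a
group's M sites are resampled with replacement B times and the score is
recomputed per replicate. By default the global central tendencies are held
fixed at their full-data values, isolating within-group sampling variability;
``recompute_ct=True`` re-estimates them per replicate from the resampled
group plus all other groups' sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contamination import central_tendency


@dataclass(slots=True)
class BootstrapResult:
    group_id: str
    point: float
    ci_low: float
    ci_high: float
    level: float
    n_replicates: int
    seed: int


def _site_values(group_table: pd.DataFrame, ct: pd.DataFrame) -> np.ndarray:
    merged = group_table.merge(ct["mean_log10"], left_on="cas",
                               right_index=True, how="inner")
    dev = merged["logc"] - merged["mean_log10"]
    return dev.groupby([merged["country"], merged["site_id"]]).mean().to_numpy()


def bootstrap_score(
    group_table: pd.DataFrame,
    ct: pd.DataFrame,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    group_id: str = "",
    recompute_ct: bool = False,
    full_table: pd.DataFrame | None = None,
    return_replicates: bool = False,
):
    """Percentile bootstrap CI for one group's contamination score.

    ``group_table`` is the group's site table (see
    :func:`pestiscore.contamination.site_table`); ``ct`` the full-data central
    tendencies. Requires M ≥ 2 sites and B ≥ 1; reproducible from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    site_ids = group_table[["country", "site_id"]].drop_duplicates()
    M = len(site_ids)
    if M < 2:
        raise ValueError("degenerate bootstrap: group has fewer than 2 sites")

    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0

    if not recompute_ct:
        vals = _site_values(group_table, ct)
        point = float(vals.mean())
        idx = rng.integers(0, M, size=(B, M))
        reps = vals[idx].mean(axis=1)
    else:
        if full_table is None:
            raise ValueError("recompute_ct requires the full site table")
        vals = _site_values(group_table, ct)
        point = float(vals.mean())
        keys = list(site_ids.itertuples(index=False, name=None))
        key_col = list(zip(group_table["country"], group_table["site_id"]))
        by_site = {k: sub for k, sub in group_table.groupby(pd.Series(key_col))}
        in_group = full_table.merge(site_ids, on=["country", "site_id"],
                                    how="left", indicator=True)
        others = in_group[in_group["_merge"] == "left_only"].drop(columns="_merge")
        reps = np.empty(B)
        for b in range(B):
            pick = rng.integers(0, M, size=M)
            parts = []
            for j, i in enumerate(pick):
                sub = by_site[keys[i]].copy()
                # relabel so resampled copies of one site stay distinct sites
                sub["site_id"] = sub["site_id"] + f"~b{j}"
                parts.append(sub)
            resampled = pd.concat(parts, ignore_index=True)
            ct_b = central_tendency(pd.concat([others, resampled],
                                              ignore_index=True))
            reps[b] = _site_values(resampled, ct_b).mean()

    ci_low, ci_high = np.quantile(reps, [alpha, 1.0 - alpha])
    result = BootstrapResult(
        group_id=group_id, point=point, ci_low=float(ci_low),
        ci_high=float(ci_high), level=level, n_replicates=B, seed=seed,
    )
    if return_replicates:
        return result, reps
    return result
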