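"""Deviation-from-global contamination scores for freshwater pesticides.

The score of a group (country or region) is the site-averaged mean deviation
of log10 concentrations from per-pesticide global central tendencies:

    S = (1/M) Σ_m (1/N_m) Σ_n [ log10 c(n, m) − mean_log10(n) ]

where ``c(n, m)`` is the reported site-mean concentration of pesticide n at
site m (the LOD, or the LOQ when the LOD is absent, substitutes for
non-detects), ``mean_log10(n)`` is the flat per-site global mean of
log10 c(n, ·), M is the number of sites in the group, and N_m the number of
pesticides with usable values at site m. S is dimensionless: S ≤ 0 means
concentrations at or below the global level, S ≥ 2 means orders of magnitude
above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .data_io import ConcentrationRecord

BAND_AT_OR_BELOW = "at_or_below_global"
BAND_SLIGHTLY_HIGHER = "slightly_higher"
BAND_SIGNIFICANTLY_HIGHER = "significantly_higher"

#: classification breakpoints on S
BAND_LOW, BAND_HIGH = 0.0, 2.0

SCORE_COLUMNS = ["group_id", "water_body", "score", "n_sites", "n_pairs", "band"]


@dataclass(slots=True)
class CentralTendency:
    """Global per-pesticide mean of log10 concentration over all sites."""

    pesticide_cas: str
    mean_log10: float
    n_sites: int


@dataclass(slots=True)
class ContaminationScore:
    group_id: str
    water_body: str
    score: float
    n_sites: int
    n_pesticide_site_pairs: int
    band: str


def classify(score: float) -> str:
    """Band a score: ≤0 at/below global, (0, 2) slightly higher, ≥2 significantly."""
    if score <= BAND_LOW:
        return BAND_AT_OR_BELOW
    if score < BAND_HIGH:
        return BAND_SLIGHTLY_HIGHER
    return BAND_SIGNIFICANTLY_HIGHER


def effective_log_concentration(record: ConcentrationRecord) -> float | None:
    """log10 of the usable concentration value of a harmonized record.

    Detected records contribute log10 of the site-mean concentration;
    non-detects contribute log10(LOD), falling back to log10(LOQ) when no LOD
    was reported. Returns None when no usable value exists (such records are
    excluded at harmonization).
    """
    if record.detected:
        if record.concentration is None or record.concentration <= 0:
            raise ValueError(
                f"non-positive detect: {record.pesticide_cas} at "
                f"{record.country}/{record.site_id}"
            )
        return math.log10(record.concentration)
    if record.lod is not None and record.lod > 0:
        return math.log10(record.lod)
    if record.loq is not None and record.loq > 0:
        return math.log10(record.loq)
    return None


def site_table(
    records: Iterable[ConcentrationRecord], water_body: str | None = None
) -> pd.DataFrame:
    """Flatten records into one row per (country, water body, site, pesticide).

    Duplicate rows for the same site × pesticide are averaged on the log10
    scale (geometric mean of concentrations), since all scoring arithmetic is
    on log values.
    """
    rows = []
    for rec in records:
        if water_body is not None and rec.water_body != water_body:
            continue
        logc = effective_log_concentration(rec)
        if logc is None:
            continue
        rows.append((rec.country, rec.region, rec.water_body, rec.site_id,
                     rec.pesticide_cas, logc))
    df = pd.DataFrame(rows, columns=["country", "region", "water_body",
                                     "site_id", "cas", "logc"])
    if df.empty:
        return df
    return (
        df.groupby(["country", "water_body", "site_id", "cas"], dropna=False)
        .agg(region=("region", "first"), logc=("logc", "mean"))
        .reset_index()
    )


def central_tendency(table: pd.DataFrame, min_sites: int = 1) -> pd.DataFrame:
    """Per-pesticide global central tendency: flat mean of log10 over all sites.

    Every site worldwide that reports the pesticide counts once, regardless of
    country. Pesticides reported at fewer than ``min_sites`` sites are dropped
    (default 1: everything retained).

    Returns a frame indexed by CAS with columns ``mean_log10`` and ``n_sites``.
    """
    if table.empty:
        raise ValueError("no records: cannot compute central tendencies")
    ct = table.groupby("cas")["logc"].agg(mean_log10="mean", n_sites="count")
    ct["n_sites"] = ct["n_sites"].astype(int)
    return ct[ct["n_sites"] >= min_sites]


def score_group(
    group_table: pd.DataFrame,
    ct: pd.DataFrame,
    group_id: str,
    water_body: str = "surface",
) -> ContaminationScore | None:
    """Score one group's site table against fixed central tendencies.

    Per site, deviations (logc − mean_log10) are averaged over the pesticides
    usable at that site; S is the flat mean of these site values over the
    group's M sites. Returns None when no site has a usable value (absent
    score, not zero).
    """
    merged = group_table.merge(
        ct["mean_log10"], left_on="cas", right_index=True, how="inner"
    )
    if merged.empty:
        return None
    merged = merged.assign(dev=merged["logc"] - merged["mean_log10"])
    site_means = merged.groupby(["country", "site_id"])["dev"].mean()
    return ContaminationScore(
        group_id=group_id,
        water_body=water_body,
        score=float(site_means.mean()),
        n_sites=int(site_means.size),
        n_pesticide_site_pairs=int(merged.shape[0]),
        band=classify(float(site_means.mean())),
    )


def _group_key(table: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "country":
        return table["country"]
    if grouping == "region":
        if table["region"].isna().all():
            raise ValueError("region grouping requested but no record has a region")
        return table["country"].str.cat(table["region"], sep=":")
    raise ValueError(f"unknown grouping {grouping!r}")


def score_all(
    records: Iterable[ConcentrationRecord] | pd.DataFrame,
    water_body: str | None = "surface",
    grouping: str = "country",
    reference: str = "global",
    min_sites: int = 1,
) -> pd.DataFrame:
    """Score every group of one water body; returns one row per group.

    ``grouping`` is ``country`` or ``region`` (admin-1 within country, keyed
    ``CCC:Region``). ``reference`` controls the population feeding the central
    tendencies: ``global`` (all records of the water body) or
    ``within_country`` (each country's own records — the internal pollution
    view used when descending from the national to the regional scale).
    """
    if isinstance(records, pd.DataFrame):
        table = records if water_body is None else records[
            records["water_body"] == water_body]
    else:
        table = site_table(records, water_body)
    if table.empty:
        raise ValueError("no usable records")
    if reference not in ("global", "within_country"):
        raise ValueError(f"unknown reference {reference!r}")

    table = table.assign(group_id=_group_key(table, grouping))
    if grouping == "region":
        table = table[table["region"].notna()]

    wb = water_body if water_body is not None else "all"
    out: list[ContaminationScore] = []
    if reference == "global":
        ct = central_tendency(table, min_sites)
        for gid, sub in table.groupby("group_id", sort=True):
            s = score_group(sub, ct, str(gid), wb)
            if s is not None:
                out.append(s)
    else:
        for country, ctable in table.groupby("country", sort=True):
            ct = central_tendency(ctable, min_sites)
            for gid, sub in ctable.groupby("group_id", sort=True):
                s = score_group(sub, ct, str(gid), wb)
                if s is not None:
                    out.append(s)

    return pd.DataFrame(
        [(s.group_id, s.water_body, s.score, s.n_sites,
          s.n_pesticide_site_pairs, s.band) for s in out],
        columns=SCORE_COLUMNS,
    )
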