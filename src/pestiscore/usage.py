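"""Pesticide usage intensity: tonnes applied per km² of agricultural land.

A country's mean intensity over a year range (default 2010–2021) is the mean
of the per-year ratios use/land over the years with both quantities reported;
missing years renormalize the denominator rather than being imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .data_io import UsageRecord

DEFAULT_YEARS = (2010, 2021)


@dataclass(slots=True)
class PUISummary:
    country: str
    mean_pui: float  # t/km² per year
    n_years: int


def compute_pui(
    usage: Iterable[UsageRecord],
    year_from: int = DEFAULT_YEARS[0],
    year_to: int = DEFAULT_YEARS[1],
) -> tuple[list[PUISummary], list[str]]:
    """Mean usage intensity per country over [year_from, year_to].

    Returns ``(summaries, skipped)`` where ``skipped`` lists countries that
    had no usable in-range year. Duplicate (country, year) rows average their
    ratios.
    """
    ratios: dict[str, dict[int, list[float]]] = {}
    seen: set[str] = set()
    for rec in usage:
        seen.add(rec.country)
        if not (year_from <= rec.year <= year_to):
            continue
        if rec.agricultural_land <= 0:
            continue
        ratios.setdefault(rec.country, {}).setdefault(rec.year, []).append(
            rec.pesticide_use / rec.agricultural_land)

    summaries = []
    for country in sorted(ratios):
        by_year = ratios[country]
        yearly = [sum(v) / len(v) for v in by_year.values()]
        summaries.append(PUISummary(
            country=country,
            mean_pui=sum(yearly) / len(yearly),
            n_years=len(by_year),
        ))
    skipped = sorted(seen - set(ratios))
    return summaries, skipped
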