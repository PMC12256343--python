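"""Hazard-quotient screening and drinking-water-standard exceedance rates.

Countries whose contamination score exceeds 2 are screened with the standard
chronic drinking-water ingestion model:

    CDI = (C × IR × EF × ED) / (BW × AT)      [mg/(kg·day)]
    HQ  = CDI / RfD

with C the concentration in mg/L, IR the daily water intake, EF/ED exposure
frequency and duration, BW body weight, AT averaging time and RfD the
chronic oral reference dose. HQ > 1 flags potential non-carcinogenic risk.

Exceedance rates compare freshwater concentrations of five commonly
regulated pesticides with national drinking-water standards, falling back to
WHO guideline values where a country sets none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contamination import effective_log_concentration
from .data_io import ConcentrationRecord, WQSRecord
from .regulation import EU_MEMBERS

#: the five commonly detected and regulated drinking-water screening pesticides
FIVE_PESTICIDE_PANEL = {
    "309-00-2": "aldrin",
    "60-57-1": "dieldrin",
    "94-75-7": "2,4-D",
    "76-44-8": "heptachlor",
    "58-89-9": "lindane",
}

EXCEEDANCE_COLUMNS = ["pesticide_cas", "scope", "n_samples", "n_exceed",
                      "rate", "standard_source"]
HQ_COLUMNS = ["country", "pesticide_cas", "concentration_used", "cdi", "rfd", "hq"]


@dataclass(slots=True)
class ExposureParams:
    """Drinking-water ingestion exposure factors (adult residential defaults)."""

    intake_rate: float = 2.0          # IR, L/day
    body_weight: float = 70.0         # BW, kg
    exposure_frequency: float = 350.0  # EF, days/year
    exposure_duration: float = 30.0   # ED, years
    averaging_time: float | None = None  # AT, days; defaults to ED × 365

    def __post_init__(self):
        if self.averaging_time is None:
            self.averaging_time = self.exposure_duration * 365.0
        if min(self.intake_rate, self.body_weight, self.exposure_frequency,
               self.exposure_duration, self.averaging_time) <= 0:
            raise ValueError("exposure parameters must be positive")
        if self.exposure_frequency > 366:
            raise ValueError("exposure_frequency exceeds days in a year")


@dataclass(slots=True)
class HQResult:
    country: str
    pesticide_cas: str
    concentration_used: float  # μg/L
    cdi: float                 # mg/(kg·day)
    rfd: float                 # mg/(kg·day)
    hq: float


@dataclass(slots=True)
class ExceedanceSummary:
    pesticide_cas: str
    scope: str  # country code or "global"
    n_samples: int
    n_exceed: int
    rate: float
    standard_source: str  # "national" | "WHO" | "mixed" (global aggregate)


def screen_high_score_groups(
    scores: pd.DataFrame, threshold: float = 2.0
) -> list[str]:
    """Group codes whose score strictly exceeds the threshold, highest first."""
    hot = scores[scores["score"] > threshold]
    hot = hot.sort_values(["score", "group_id"], ascending=[False, True])
    return hot["group_id"].tolist()


def hazard_quotient(
    concentration_ug_l: float,
    params: ExposureParams,
    rfd: float,
    country: str = "",
    pesticide_cas: str = "",
) -> HQResult:
    """HQ of one concentration against one reference dose."""
    if rfd <= 0:
        raise ValueError("reference dose must be positive")
    if concentration_ug_l < 0:
        raise ValueError("negative concentration")
    c_mg_l = concentration_ug_l / 1000.0
    cdi = (c_mg_l * params.intake_rate * params.exposure_frequency
           * params.exposure_duration) / (params.body_weight
                                          * params.averaging_time)
    return HQResult(country=country, pesticide_cas=pesticide_cas,
                    concentration_used=concentration_ug_l,
                    cdi=cdi, rfd=rfd, hq=cdi / rfd)


def hq_screen(
    records: Iterable[ConcentrationRecord],
    high_score_groups: Sequence[str],
    rfd_table: Mapping[str, float],
    params: ExposureParams | None = None,
    statistic: str = "max",
) -> pd.DataFrame:
    """Hazard quotients for every pesticide with an RfD in each screened country.

    ``statistic`` picks the exposure concentration per country × pesticide:
    the maximum detected site mean (``max``, the peak-exposure screen) or the
    arithmetic mean of detected site means (``mean``).
    """
    if statistic not in ("max", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    params = params or ExposureParams()
    groups = set(high_score_groups)
    rows: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if rec.country not in groups or not rec.detected:
            continue
        if rec.pesticide_cas not in rfd_table or rec.concentration is None:
            continue
        rows.setdefault((rec.country, rec.pesticide_cas), []).append(
            rec.concentration)
    out = []
    for (country, cas), concs in sorted(rows.items()):
        c = max(concs) if statistic == "max" else sum(concs) / len(concs)
        r = hazard_quotient(c, params, rfd_table[cas], country, cas)
        out.append((r.country, r.pesticide_cas, r.concentration_used,
                    r.cdi, r.rfd, r.hq))
    return pd.DataFrame(out, columns=HQ_COLUMNS)


def _national_standards(
    drinking_standards: Iterable[WQSRecord],
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for r in drinking_standards:
        if r.medium != "drinking":
            continue
        key = (r.jurisdiction, r.pesticide_cas)
        out[key] = min(r.value, out.get(key, float("inf")))
    return out


def exceedance_rates(
    records: Iterable[ConcentrationRecord],
    drinking_standards: Iterable[WQSRecord],
    who_table: Mapping[str, float],
    pesticides: Sequence[str] | None = None,
    exclude_eu: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Fraction of samples above the applicable drinking-water standard.

    Per pesticide × country and per pesticide globally. Detected records
    exceed when concentration is strictly greater than the standard;
    non-detects count as non-exceeding at their LOD/LOQ unless that limit
    itself exceeds the standard, in which case the record is indeterminate
    and excluded from both numerator and denominator. Countries lacking both
    a national and a WHO standard for a pesticide are excluded and reported
    in the second return value.
    """
    panel = list(pesticides if pesticides is not None else FIVE_PESTICIDE_PANEL)
    national = _national_standards(drinking_standards)
    eu = set(EU_MEMBERS) if exclude_eu else set()

    counts: dict[tuple[str, str], list[int]] = {}
    sources: dict[tuple[str, str], str] = {}
    missing: list[tuple[str, str]] = []
    missing_seen: set[tuple[str, str]] = set()

    for rec in records:
        cas = rec.pesticide_cas
        if cas not in panel or rec.country in eu:
            continue
        key = (cas, rec.country)
        if key in missing_seen:
            continue
        std_nat = national.get((rec.country, cas))
        if std_nat is not None:
            std, source = std_nat, "national"
        elif cas in who_table:
            std, source = who_table[cas], "WHO"
        else:
            missing.append(key)
            missing_seen.add(key)
            continue
        logc = effective_log_concentration(rec)
        if logc is None:
            continue
        value = rec.concentration if rec.detected else (rec.lod or rec.loq)
        if not rec.detected and value is not None and value > std:
            continue  # indeterminate: censoring limit above the standard
        n, x = counts.get(key, (0, 0))
        exceed = 1 if (rec.detected and value is not None and value > std) else 0
        counts[key] = [n + 1, x + exceed]
        sources[key] = source

    rows = []
    global_counts: dict[str, list] = {}
    for (cas, country), (n, x) in sorted(counts.items()):
        rows.append((cas, country, n, x, x / n, sources[(cas, country)]))
        g = global_counts.setdefault(cas, [0, 0, set()])
        g[0] += n
        g[1] += x
        g[2].add(sources[(cas, country)])
    for cas in sorted(global_counts):
        n, x, srcs = global_counts[cas]
        source = srcs.pop() if len(srcs) == 1 else "mixed"
        rows.append((cas, "global", n, x, x / n, source))
    df = pd.DataFrame(rows, columns=EXCEEDANCE_COLUMNS)
    return df, missing
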