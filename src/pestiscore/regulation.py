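"""National pesticide regulation scores over a 30-pesticide panel.

Completeness (CS) counts how many panel pesticides a jurisdiction regulates
in a medium. Three numeric stringency scores compare the jurisdiction's
standard values with the global distribution of standards for each pesticide
(all on log10 of the value in μg/L):

- NS1: Σ 1 − Φ((log10 WQS − μ_i) / σ_i) — the total probability that a random
  standard drawn from a log-normal fit exceeds the jurisdiction's standard.
  Only meaningful when the log standards pass a normality prerequisite
  (Shapiro–Wilk), which is checked and reported; the score carries a validity
  flag rather than being silently dropped.
- NS2: Σ of 1 − (log10 WQS − min_i) / (max_i − min_i), the min–max relative
  position between the global extremes (1 = strictest, 0 = laxest), each term
  clamped to [0, 1].
- NS3: mean of (log10 WQS − μ_i) over the N pesticides the jurisdiction
  regulates; lower (more negative) = stricter.

When a jurisdiction maintains several standards systems for one medium, only
the most conservative system enters the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import WQSRecord

#: EU member states (alpha-3) inheriting bloc-level standards when no
#: national row exists. Bloc rows use jurisdiction "EU".
EU_MEMBERS = [
    "AUT", "BEL", "BGR", "HRV", "CYP", "CZE", "DNK", "EST", "FIN", "FRA",
    "DEU", "GRC", "HUN", "IRL", "ITA", "LVA", "LTU", "LUX", "MLT", "NLD",
    "POL", "PRT", "ROU", "SVK", "SVN", "ESP", "SWE",
]

REGULATION_COLUMNS = ["jurisdiction", "medium", "cs", "ns1", "ns1_valid",
                      "ns2", "ns3", "n_regulated"]


@dataclass(slots=True)
class RegulationScores:
    jurisdiction: str
    medium: str
    cs: int
    ns1: float | None
    ns1_valid: bool
    ns2: float
    ns3: float | None
    n_regulated: int


@dataclass(slots=True)
class NormalityReport:
    pesticide_cas: str
    n_values: int
    p_value: float  # NaN when the test could not be run
    normal_at_005: bool
    note: str = ""


# ---------------------------------------------------------------------------
# system selection and bloc expansion
# ---------------------------------------------------------------------------

def select_conservative_system(
    wqs: Iterable[WQSRecord], jurisdiction: str, medium: str
) -> list[WQSRecord]:
    """Keep one standards system per jurisdiction × medium: the most conservative.

    A system uniformly dominated by another (lower values throughout) is
    dropped; when systems do not dominate each other, the one with the lower
    mean log10 value over its regulated pesticides wins, with a lexical
    tie-break on system_id for determinism.
    """
    recs = [r for r in wqs
            if r.jurisdiction == jurisdiction and r.medium == medium]
    if not recs:
        return []
    systems = sorted({r.system_id for r in recs})
    if len(systems) == 1:
        return recs

    def mean_log(system: str) -> float:
        vals = [np.log10(r.value) for r in recs if r.system_id == system]
        return float(np.mean(vals))

    best = min(systems, key=lambda s: (mean_log(s), s))
    return [r for r in recs if r.system_id == best]


def expand_eu_bloc(
    wqs: Iterable[WQSRecord],
    bloc_id: str = "EU",
    members: Sequence[str] = EU_MEMBERS,
) -> list[WQSRecord]:
    """Give each member state the bloc's standards where it has no national row.

    A member that regulates a pesticide nationally keeps its own value; bloc
    rows fill only the gaps (per pesticide × medium). The bloc pseudo-
    jurisdiction itself is removed from the output.
    """
    wqs = list(wqs)
    bloc_rows = [r for r in wqs if r.jurisdiction == bloc_id]
    out = [r for r in wqs if r.jurisdiction != bloc_id]
    national = {(r.jurisdiction, r.pesticide_cas, r.medium) for r in out}
    for member in members:
        for row in bloc_rows:
            key = (member, row.pesticide_cas, row.medium)
            if key not in national:
                out.append(WQSRecord(member, row.pesticide_cas, row.medium,
                                     row.value, system_id=f"{bloc_id}:{row.system_id}"))
    return out


def _selected_frame(
    wqs: Iterable[WQSRecord], medium: str, panel: Sequence[str]
) -> pd.DataFrame:
    """Long frame of log10 standards after system selection, one row per
    jurisdiction × panel pesticide (the minimum value if a system repeats a
    pesticide)."""
    wqs = [r for r in wqs if r.medium == medium and r.pesticide_cas in set(panel)]
    rows = []
    for jur in sorted({r.jurisdiction for r in wqs}):
        for r in select_conservative_system(wqs, jur, medium):
            rows.append((r.jurisdiction, r.pesticide_cas, np.log10(r.value)))
    df = pd.DataFrame(rows, columns=["jurisdiction", "cas", "log_wqs"])
    if df.empty:
        return df
    return df.groupby(["jurisdiction", "cas"], as_index=False)["log_wqs"].min()


def global_log_stats(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-pesticide μ, σ (ddof=1), min, max and jurisdiction count of log10 WQS."""
    g = frame.groupby("cas")["log_wqs"]
    out = g.agg(mu="mean", sigma=lambda x: x.std(ddof=1),
                lo="min", hi="max", n="count")
    out["sigma"] = out["sigma"].fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# individual scores
# ---------------------------------------------------------------------------

def completeness_score(selected: Iterable[WQSRecord], panel: Sequence[str]) -> int:
    """Count of panel pesticides with a standard in the selected system."""
    regulated = {r.pesticide_cas for r in selected}
    return sum(1 for cas in panel if cas in regulated)


def _jurisdiction_logs(selected: Iterable[WQSRecord],
                       panel: Sequence[str]) -> dict[str, float]:
    logs: dict[str, float] = {}
    for r in selected:
        if r.pesticide_cas in set(panel):
            v = np.log10(r.value)
            logs[r.pesticide_cas] = min(v, logs.get(r.pesticide_cas, np.inf))
    return logs


def ns1(
    selected: Iterable[WQSRecord],
    global_wqs: pd.DataFrame,
    panel: Sequence[str],
    normality: Sequence[NormalityReport] | None = None,
) -> tuple[float | None, bool]:
    """Log-normal exceedance-probability stringency sum, with validity flag.

    Returns ``(score, valid)``. ``valid`` is False when any tested pesticide
    rejects normality of log standards at α = 0.05 — the score is still
    computed for inspection but should not be reported.
    """
    logs = _jurisdiction_logs(selected, panel)
    if not logs:
        return None, _ns1_validity(normality)
    total = 0.0
    for cas, lw in logs.items():
        if cas not in global_wqs.index:
            continue
        mu, sigma, n = global_wqs.loc[cas, ["mu", "sigma", "n"]]
        if n < 2 or sigma == 0:
            warnings.warn(f"NS1: sigma undefined for {cas}; term skipped")
            continue
        total += 1.0 - stats.norm.cdf((lw - mu) / sigma)
    return total, _ns1_validity(normality)


def _ns1_validity(normality: Sequence[NormalityReport] | None) -> bool:
    if normality is None:
        return True
    tested = [r for r in normality if not np.isnan(r.p_value)]
    return all(r.normal_at_005 for r in tested)


def ns2(
    selected: Iterable[WQSRecord],
    global_wqs: pd.DataFrame,
    panel: Sequence[str],
) -> float:
    """Min–max relative-position stringency sum (1 per pesticide = strictest)."""
    logs = _jurisdiction_logs(selected, panel)
    total = 0.0
    for cas, lw in logs.items():
        if cas not in global_wqs.index:
            continue
        lo, hi = global_wqs.loc[cas, ["lo", "hi"]]
        if hi == lo:
            warnings.warn(f"NS2: degenerate range for {cas}; neutral 0.5 term")
            total += 0.5
            continue
        term = 1.0 - (lw - lo) / (hi - lo)
        total += min(1.0, max(0.0, term))
    return total


def ns3(
    selected: Iterable[WQSRecord],
    global_wqs: pd.DataFrame,
    panel: Sequence[str],
) -> float | None:
    """Mean log10 deviation from the global per-pesticide mean standard."""
    logs = _jurisdiction_logs(selected, panel)
    devs = [lw - global_wqs.loc[cas, "mu"]
            for cas, lw in logs.items() if cas in global_wqs.index]
    if not devs:
        return None
    return float(np.mean(devs))


def normality_check(
    wqs: Iterable[WQSRecord],
    medium: str,
    panel: Sequence[str],
    pooled: bool = False,
) -> list[NormalityReport]:
    """Shapiro–Wilk on log10 standards, per pesticide (or pooled across them).

    Pesticides with fewer than 3 values, or zero variance, are skipped with a
    reason; the NS1 prerequisite fails when any tested pesticide rejects at
    α = 0.05.
    """
    frame = _selected_frame(wqs, medium, panel)
    if frame.empty:
        return []
    groups = ([("pooled", frame["log_wqs"])] if pooled
              else [(cas, sub["log_wqs"]) for cas, sub in frame.groupby("cas")])
    reports = []
    for cas, vals in groups:
        vals = vals.to_numpy()
        if len(vals) < 3:
            reports.append(NormalityReport(str(cas), len(vals), float("nan"),
                                           False, "fewer than 3 values"))
            continue
        if np.ptp(vals) == 0:
            reports.append(NormalityReport(str(cas), len(vals), float("nan"),
                                           False, "zero variance"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = stats.shapiro(vals)
        reports.append(NormalityReport(str(cas), len(vals),
                                       float(stat.pvalue),
                                       bool(stat.pvalue >= 0.05)))
    return reports


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def compute_regulation_scores(
    wqs: Iterable[WQSRecord],
    medium: str,
    panel: Sequence[str],
    expand_bloc: bool = True,
    pooled_normality: bool = False,
) -> tuple[pd.DataFrame, list[NormalityReport]]:
    """CS and NS1–NS3 for every jurisdiction regulating ≥0 panel pesticides.

    Jurisdictions present in the table but regulating none of the panel get
    CS = 0 with absent numeric scores. The jurisdiction being scored is
    included in the global statistics (no leave-one-out).
    """
    wqs = list(wqs)
    if expand_bloc:
        wqs = expand_eu_bloc(wqs)
    medium_wqs = [r for r in wqs if r.medium == medium]
    frame = _selected_frame(medium_wqs, medium, panel)
    gstats = global_log_stats(frame) if not frame.empty else pd.DataFrame(
        columns=["mu", "sigma", "lo", "hi", "n"])
    reports = normality_check(medium_wqs, medium, panel, pooled=pooled_normality)
    valid = _ns1_validity(reports)

    rows = []
    for jur in sorted({r.jurisdiction for r in medium_wqs}):
        selected = select_conservative_system(
            [r for r in medium_wqs if r.pesticide_cas in set(panel)],
            jur, medium)
        cs = completeness_score(selected, panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, _ = ns1(selected, gstats, panel, reports)
            s2 = ns2(selected, gstats, panel)
            s3 = ns3(selected, gstats, panel)
        rows.append((jur, medium, cs, s1, valid, s2, s3, cs))
    df = pd.DataFrame(rows, columns=REGULATION_COLUMNS)
    return df, reports
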