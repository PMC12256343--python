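"""Shared test helpers: record factories and independent brute-force oracles.

The oracles deliberately avoid the package's own code paths (pure-Python
loops, math.erfc for the normal CDF, rank-then-Pearson for Spearman) so they
can serve as independent references for the vectorized implementations.
"""

from __future__ import annotations

import math
from collections import defaultdict

from pestiscore.data_io import ConcentrationRecord, WQSRecord


def make_record(country="AAA", site="s1", cas="1912-24-9", conc=1.0,
                water_body="surface", detected=True, lod=None, loq=None,
                year=2015, name="", region=None, is_mixture=False):
    return ConcentrationRecord(
        country=country, water_body=water_body, site_id=site,
        pesticide_cas=cas, pesticide_name=name, concentration=conc,
        detected=detected, lod=lod, loq=loq, year_start=year, year_end=year,
        region=region, is_mixture=is_mixture,
    )


def records_from_logs(data):
    """Build detected records from {country: {site: {cas: log10 conc}}}."""
    records = []
    for country, sites in data.items():
        for site, per_cas in sites.items():
            for cas, logc in per_cas.items():
                records.append(make_record(country=country, site=site,
                                           cas=cas, conc=10.0 ** logc))
    return records


def brute_force_scores(data):
    """Direct evaluation of the contamination score definition.

    ``data`` is {country: {site: {cas: log10 value}}}. The global central
    tendency of each pesticide is the flat mean over every site reporting it;
    each site contributes the mean deviation over its own pesticides; each
    country the mean over its sites.
    """
    per_pesticide = defaultdict(list)
    for sites in data.values():
        for per_cas in sites.values():
            for cas, logc in per_cas.items():
                per_pesticide[cas].append(logc)
    ct = {cas: sum(v) / len(v) for cas, v in per_pesticide.items()}

    scores = {}
    for country, sites in data.items():
        site_vals = []
        for per_cas in sites.values():
            devs = [logc - ct[cas] for cas, logc in per_cas.items()]
            site_vals.append(sum(devs) / len(devs))
        scores[country] = sum(site_vals) / len(site_vals)
    return scores


def phi(z):
    """Standard normal CDF via the complementary error function."""
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def brute_force_regulation(wqs_logs, panel):
    """Direct evaluation of CS and the three stringency sums.

    ``wqs_logs`` is {jurisdiction: {cas: log10 standard}} (one conservative
    system per jurisdiction already). Returns per jurisdiction a dict with
    cs, ns1, ns2, ns3 (ns1 terms skipped where sigma is undefined; ns2
    degenerate ranges contribute the neutral 0.5).
    """
    by_cas = defaultdict(list)
    for logs in wqs_logs.values():
        for cas, lw in logs.items():
            if cas in panel:
                by_cas[cas].append(lw)
    stats = {}
    for cas, vals in by_cas.items():
        mu = sum(vals) / len(vals)
        if len(vals) >= 2:
            var = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
            sigma = math.sqrt(var)
        else:
            sigma = 0.0
        stats[cas] = (mu, sigma, min(vals), max(vals), len(vals))

    out = {}
    for jur, logs in wqs_logs.items():
        regulated = [cas for cas in panel if cas in logs]
        cs = len(regulated)
        ns1 = ns2 = 0.0
        devs = []
        for cas in regulated:
            mu, sigma, lo, hi, n = stats[cas]
            lw = logs[cas]
            if n >= 2 and sigma > 0:
                ns1 += 1.0 - phi((lw - mu) / sigma)
            if hi == lo:
                ns2 += 0.5
            else:
                ns2 += min(1.0, max(0.0, 1.0 - (lw - lo) / (hi - lo)))
            devs.append(lw - mu)
        ns3 = sum(devs) / len(devs) if devs else None
        out[jur] = {"cs": cs, "ns1": ns1, "ns2": ns2, "ns3": ns3}
    return out


def wqs_records_from_logs(wqs_logs, medium="surface", system_id="SYS"):
    return [
        WQSRecord(jur, cas, medium, 10.0 ** lw, system_id=system_id)
        for jur, logs in wqs_logs.items() for cas, lw in logs.items()
    ]


def brute_force_spearman(x, y):
    """Spearman's rho: average ranks, then the Pearson formula by hand."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def brute_force_descending_ranks(scores):
    """{group: average descending rank} by explicit sorting (rank 1 = highest)."""
    items = list(scores.items())
    ranks = {}
    for gid, s in items:
        higher = sum(1 for _, t in items if t > s)
        equal = sum(1 for _, t in items if t == s)
        ranks[gid] = higher + (equal + 1) / 2.0
    return ranks
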