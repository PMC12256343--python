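import math
import warnings

import numpy as np
import pytest

from pestiscore.data_io import WQSRecord
from pestiscore.regulation import (
    _selected_frame,
    completeness_score,
    compute_regulation_scores,
    expand_eu_bloc,
    global_log_stats,
    normality_check,
    ns1,
    ns2,
    ns3,
    select_conservative_system,
)

from helpers import brute_force_regulation, wqs_records_from_logs

PANEL3 = ["1912-24-9", "94-75-7", "58-89-9"]


def _stats(wqs_logs, panel):
    frame = _selected_frame(wqs_records_from_logs(wqs_logs), "surface", panel)
    return global_log_stats(frame)


class TestConservativeSystem:
    def test_single_system_returned_unchanged(self):
        wqs = [WQSRecord("CHN", "1912-24-9", "surface", 3.0, "GB")]
        assert select_conservative_system(wqs, "CHN", "surface") == wqs

    def test_uniformly_lower_system_wins(self):
        wqs = (
            [WQSRecord("CHN", cas, "surface", 1.0, "A") for cas in PANEL3]
            + [WQSRecord("CHN", cas, "surface", 10.0, "B") for cas in PANEL3]
        )
        sel = select_conservative_system(wqs, "CHN", "surface")
        assert {r.system_id for r in sel} == {"A"}

    def test_non_dominating_tiebreak_by_mean_log(self):
        # A: log values {0, 2} mean 1; B: {1.2, 0.2} mean 0.7 → B wins
        wqs = [
            WQSRecord("CHN", "1912-24-9", "surface", 1.0, "A"),
            WQSRecord("CHN", "94-75-7", "surface", 100.0, "A"),
            WQSRecord("CHN", "1912-24-9", "surface", 10.0 ** 1.2, "B"),
            WQSRecord("CHN", "94-75-7", "surface", 10.0 ** 0.2, "B"),
        ]
        sel = select_conservative_system(wqs, "CHN", "surface")
        assert {r.system_id for r in sel} == {"B"}

    def test_exact_tie_broken_lexically(self):
        wqs = [
            WQSRecord("CHN", "1912-24-9", "surface", 1.0, "Z"),
            WQSRecord("CHN", "1912-24-9", "surface", 1.0, "A"),
        ]
        sel = select_conservative_system(wqs, "CHN", "surface")
        assert sel[0].system_id == "A"

    def test_empty_input_empty_output(self):
        assert select_conservative_system([], "CHN", "surface") == []


class TestCompleteness:
    def test_counts_panel_pesticides(self):
        panel = [f"p{i}" for i in range(30)]
        selected = [WQSRecord("IRL", cas, "surface", 1.0) for cas in panel]
        assert completeness_score(selected, panel) == 30
        assert completeness_score([], panel) == 0
        assert completeness_score(selected[:7], panel) == 7

    def test_off_panel_standards_do_not_count(self):
        selected = [WQSRecord("CHN", "999-99-9", "surface", 1.0)]
        assert completeness_score(selected, PANEL3) == 0


class TestStringencyScores:
    def test_ns1_term_half_at_global_mean(self):
        logs = {"AAA": {"1912-24-9": 0.0}, "BBB": {"1912-24-9": 2.0},
                "CCC": {"1912-24-9": -2.0}}
        stats = _stats(logs, PANEL3)
        sel = wqs_records_from_logs({"AAA": {"1912-24-9": 0.0}})
        score, _ = ns1(sel, stats, PANEL3)
        assert score == pytest.approx(0.5)

    def test_ns1_term_approaches_one_for_vanishing_standard(self):
        # global stats held fixed: the term 1 − Φ((log WQS − μ)/σ) → 1
        # as the standard value → 0⁺ (log → −∞)
        logs = {"BBB": {"1912-24-9": 0.0}, "CCC": {"1912-24-9": 1.0},
                "DDD": {"1912-24-9": -1.0}}
        stats = _stats(logs, PANEL3)
        sel = wqs_records_from_logs({"AAA": {"1912-24-9": -30.0}})
        score, _ = ns1(sel, stats, PANEL3)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_ns2_extremes(self):
        logs = {"AAA": {"1912-24-9": -1.0}, "BBB": {"1912-24-9": 0.0},
                "CCC": {"1912-24-9": 1.0}}
        stats = _stats(logs, PANEL3)
        strict = ns2(wqs_records_from_logs({"AAA": {"1912-24-9": -1.0}}),
                     stats, PANEL3)
        lax = ns2(wqs_records_from_logs({"CCC": {"1912-24-9": 1.0}}),
                  stats, PANEL3)
        assert strict == pytest.approx(1.0)
        assert lax == pytest.approx(0.0)

    def test_ns2_degenerate_range_neutral(self):
        logs = {j: {"1912-24-9": 0.5} for j in ("AAA", "BBB", "CCC")}
        stats = _stats(logs, PANEL3)
        with pytest.warns(UserWarning, match="degenerate"):
            score = ns2(wqs_records_from_logs({"AAA": {"1912-24-9": 0.5}}),
                        stats, PANEL3)
        assert score == pytest.approx(0.5)

    def test_ns3_zero_at_global_mean_and_shift(self):
        logs = {"AAA": {c: 0.0 for c in PANEL3},
                "BBB": {c: 1.0 for c in PANEL3},
                "CCC": {c: -1.0 for c in PANEL3}}
        stats = _stats(logs, PANEL3)
        at_mean = ns3(wqs_records_from_logs({"X": {c: 0.0 for c in PANEL3}}),
                      stats, PANEL3)
        stricter = ns3(wqs_records_from_logs({"X": {c: -1.0 for c in PANEL3}}),
                       stats, PANEL3)
        assert at_mean == pytest.approx(0.0)
        assert stricter == pytest.approx(-1.0)

    def test_ns3_absent_with_nothing_regulated(self):
        logs = {"AAA": {"1912-24-9": 0.0}, "BBB": {"1912-24-9": 1.0}}
        stats = _stats(logs, PANEL3)
        assert ns3([], stats, PANEL3) is None

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            jurs = [f"J{i}" for i in range(rng.integers(2, 5))]
            panel = PANEL3[: rng.integers(1, 4)]
            logs = {}
            for j in jurs:
                regulated = [c for c in panel if rng.random() < 0.8]
                logs[j] = {c: float(rng.normal(0, 1)) for c in regulated}
            logs = {j: v for j, v in logs.items() if v}
            if len(logs) < 2:
                continue
            expected = brute_force_regulation(logs, panel)
            stats = _stats(logs, panel)
            for j, exp in expected.items():
                sel = wqs_records_from_logs({j: logs[j]})
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s1, _ = ns1(sel, stats, panel)
                    s2 = ns2(sel, stats, panel)
                    s3 = ns3(sel, stats, panel)
                assert completeness_score(sel, panel) == exp["cs"]
                assert s1 == pytest.approx(exp["ns1"], abs=1e-12)
                assert s2 == pytest.approx(exp["ns2"], abs=1e-12)
                if exp["ns3"] is None:
                    assert s3 is None
                else:
                    assert s3 == pytest.approx(exp["ns3"], abs=1e-12)

    def test_lowering_standard_never_relaxes_scores(self):
        """Anti-monotonicity: a stricter (lower) standard cannot lower NS1/NS2
        or raise NS3 when the jurisdiction is not already the extremum."""
        logs = {"AAA": {"1912-24-9": 0.0}, "BBB": {"1912-24-9": 1.0},
                "CCC": {"1912-24-9": -1.0}}
        panel = ["1912-24-9"]

        def scores_for(value):
            mod = {**logs, "AAA": {"1912-24-9": value}}
            stats = _stats(mod, panel)
            sel = wqs_records_from_logs({"AAA": mod["AAA"]})
            s1, _ = ns1(sel, stats, panel)
            return s1, ns2(sel, stats, panel), ns3(sel, stats, panel)

        base = scores_for(0.0)
        strict = scores_for(-0.5)
        assert strict[0] >= base[0]
        assert strict[1] >= base[1]
        assert strict[2] <= base[2]


class TestNormalityCheck:
    def test_lognormal_sample_usually_accepted(self):
        rng = np.random.default_rng(0)
        logs = {f"J{i}": {"1912-24-9": float(v)}
                for i, v in enumerate(rng.normal(0, 1, size=50))}
        reports = normality_check(wqs_records_from_logs(logs), "surface",
                                  PANEL3)
        assert reports[0].normal_at_005

    def test_identical_values_skipped(self):
        logs = {f"J{i}": {"1912-24-9": 0.5} for i in range(5)}
        reports = normality_check(wqs_records_from_logs(logs), "surface",
                                  PANEL3)
        assert math.isnan(reports[0].p_value)
        assert reports[0].note == "zero variance"

    def test_too_few_values_skipped_with_reason(self):
        logs = {"J0": {"1912-24-9": 0.1}, "J1": {"1912-24-9": 0.4}}
        reports = normality_check(wqs_records_from_logs(logs), "surface",
                                  PANEL3)
        assert reports[0].note == "fewer than 3 values"

    def test_bimodal_sample_rejected(self):
        vals = [-5.0 + 0.01 * i for i in range(10)] + \
               [5.0 + 0.01 * i for i in range(10)]
        logs = {f"J{i}": {"1912-24-9": v} for i, v in enumerate(vals)}
        reports = normality_check(wqs_records_from_logs(logs), "surface",
                                  PANEL3)
        assert not reports[0].normal_at_005
        assert reports[0].p_value < 0.05

    def test_type_i_error_rate_near_alpha(self):
        """Exact log-normal standards reject at roughly the 5% nominal rate."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_trials = 200
        for _ in range(n_trials):
            logs = {f"J{i}": {"1912-24-9": float(v)}
                    for i, v in enumerate(rng.normal(0, 1, size=50))}
            reports = normality_check(wqs_records_from_logs(logs), "surface",
                                      ["1912-24-9"])
            rejections += not reports[0].normal_at_005
        assert 0.005 <= rejections / n_trials <= 0.12


class TestDriver:
    def test_cs_equals_n_regulated_and_bounds(self):
        rng = np.random.default_rng(5)
        panel = PANEL3
        logs = {f"J{i}": {c: float(rng.normal()) for c in panel
                          if rng.random() < 0.7} for i in range(4)}
        wqs = wqs_records_from_logs({j: v for j, v in logs.items() if v})
        scores, _ = compute_regulation_scores(wqs, "surface", panel,
                                              expand_bloc=False)
        assert (scores["cs"] == scores["n_regulated"]).all()
        assert scores["cs"].between(0, 30).all()
        valid_ns2 = scores["ns2"].dropna()
        assert ((0 <= valid_ns2) & (valid_ns2 <= scores["n_regulated"])).all()

    def test_eu_members_inherit_bloc_standards(self):
        wqs = [WQSRecord("EU", "1912-24-9", "ground", 0.1, "WFD"),
               WQSRecord("FRA", "1912-24-9", "ground", 0.5, "NAT"),
               WQSRecord("CHN", "1912-24-9", "ground", 1.0, "GB")]
        expanded = expand_eu_bloc(wqs)
        by_jur = {r.jurisdiction: r for r in expanded
                  if r.pesticide_cas == "1912-24-9"}
        assert by_jur["DEU"].value == pytest.approx(0.1)   # inherited
        assert by_jur["FRA"].value == pytest.approx(0.5)   # national kept
        assert "EU" not in by_jur

    def test_ns1_invalidated_by_non_normal_standards(self):
        vals = [-5.0 + 0.01 * i for i in range(10)] + \
               [5.0 + 0.01 * i for i in range(10)]
        logs = {f"J{i}": {"1912-24-9": v} for i, v in enumerate(vals)}
        scores, reports = compute_regulation_scores(
            wqs_records_from_logs(logs), "surface", ["1912-24-9"],
            expand_bloc=False)
        assert not scores["ns1_valid"].any()
        assert any(not r.normal_at_005 for r in reports)
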