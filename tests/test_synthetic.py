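import numpy as np
import pytest

from pestiscore.contamination import central_tendency, score_all, site_table
from pestiscore.data_io import harmonize_records, records_to_frame
from pestiscore.synthetic import (
    CountrySpec,
    PesticideSpec,
    SyntheticConfig,
    default_config,
    default_ground_config,
    expected_scores,
    generate_dataset,
    generate_usage,
    generate_wqs,
    load_config,
)


def _config(**kw):
    base = dict(
        countries=[CountrySpec("AAA", 4, 1.0), CountrySpec("BBB", 4, -1.0)],
        pesticides=[PesticideSpec("1912-24-9", -1.0, 0.0),
                    PesticideSpec("94-75-7", -2.0, 0.0)],
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerateDataset:
    def test_degenerate_noise_reproduces_offsets_exactly(self):
        records = generate_dataset(_config())
        for rec in records:
            expected = {"AAA": 1.0, "BBB": -1.0}[rec.country]
            base = {"1912-24-9": -1.0, "94-75-7": -2.0}[rec.pesticide_cas]
            assert np.log10(rec.concentration) == pytest.approx(base + expected)

    def test_same_seed_identical_output(self):
        a = generate_dataset(default_config(5))
        b = generate_dataset(default_config(5))
        assert records_to_frame(a).equals(records_to_frame(b))

    def test_different_seed_differs(self):
        a = generate_dataset(default_config(5))
        b = generate_dataset(default_config(6))
        assert not records_to_frame(a).equals(records_to_frame(b))

    def test_censoring_fraction_binomial(self):
        cfg = _config(countries=[CountrySpec("AAA", 500, 0.0)],
                      pesticides=[PesticideSpec("1912-24-9", -1.0, 0.3)] * 1,
                      censor_quantile=0.3)
        cfg.pesticides = [PesticideSpec(f"p{i}", -1.0, 0.3) for i in range(20)]
        records = generate_dataset(cfg)
        assert len(records) == 10_000
        frac = sum(not r.detected for r in records) / len(records)
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_censored_records_carry_lod(self):
        cfg = _config(censor_quantile=1.0, lod_log10=-2.5)
        for rec in generate_dataset(cfg):
            assert not rec.detected and rec.concentration is None
            assert rec.lod == pytest.approx(10 ** -2.5)

    def test_panel_coverage_thins_records(self):
        cfg = _config(panel_coverage=0.5, seed=3)
        full = _config(panel_coverage=1.0, seed=3)
        assert len(generate_dataset(cfg)) < len(generate_dataset(full))

    def test_records_pass_harmonization(self):
        records = generate_dataset(default_config(2))
        result = harmonize_records(records)
        assert not result.excluded


class TestExpectedScores:
    def test_two_equal_countries_symmetric(self):
        exp = expected_scores(_config()).set_index("group_id")
        assert exp.loc["AAA", "expected_score"] == pytest.approx(1.0)
        assert exp.loc["BBB", "expected_score"] == pytest.approx(-1.0)

    def test_equal_offsets_all_zero(self):
        cfg = _config(countries=[CountrySpec("AAA", 3, 0.4),
                                 CountrySpec("BBB", 9, 0.4)])
        exp = expected_scores(cfg)
        assert np.allclose(exp["expected_score"], 0.0)

    def test_site_weighted_mean_is_zero(self):
        cfg = _config(countries=[CountrySpec("AAA", 3, 1.0),
                                 CountrySpec("BBB", 9, -0.2),
                                 CountrySpec("CCC", 5, 0.7)])
        exp = expected_scores(cfg)
        assert (exp["expected_score"] * exp["n_sites"]).sum() == \
            pytest.approx(0.0, abs=1e-12)

    def test_noise_free_scorer_recovers_expectation_exactly(self):
        cfg = _config(countries=[CountrySpec("AAA", 2, 0.8),
                                 CountrySpec("BBB", 6, -0.3)])
        scores = score_all(generate_dataset(cfg)).set_index("group_id")
        exp = expected_scores(cfg).set_index("group_id")
        for c in exp.index:
            assert scores.loc[c, "score"] == pytest.approx(
                exp.loc[c, "expected_score"], abs=1e-12)

    def test_refuses_censoring_or_partial_coverage(self):
        with pytest.raises(ValueError, match="censoring"):
            expected_scores(_config(censor_quantile=0.2))
        with pytest.raises(ValueError, match="coverage"):
            expected_scores(_config(panel_coverage=0.9))

    def test_censoring_at_high_lod_never_decreases_scores(self):
        """Replacing values with a LOD above them can only raise log values,
        so no country's deviation-sum drops on the shared-panel design."""
        cfg = _config(countries=[CountrySpec("AAA", 5, 0.5),
                                 CountrySpec("BBB", 5, -0.5)],
                      pesticides=[PesticideSpec("1912-24-9", -2.0, 0.2)])
        records = generate_dataset(cfg)
        base = score_all(records).set_index("group_id")["score"]
        lod = 10.0  # above every generated value
        censored = []
        for rec in records:
            if rec.country == "BBB":
                r = type(rec)(**{f: getattr(rec, f) for f in
                                 rec.__dataclass_fields__})
                r.detected, r.concentration, r.lod = False, None, lod
                censored.append(r)
            else:
                censored.append(rec)
        after = score_all(censored).set_index("group_id")["score"]
        assert after["BBB"] >= base["BBB"]


class TestParameterRecovery:
    def test_scores_within_three_mc_standard_errors(self):
        """σ=0.3, 30 sites/country, no censoring: mean estimated scores match
        the closed form within 3 Monte-Carlo SEs over seeded replicates."""
        cfg = _config(
            countries=[CountrySpec("AAA", 30, 0.6),
                       CountrySpec("BBB", 30, -0.2),
                       CountrySpec("CCC", 30, -0.4)],
            pesticides=[PesticideSpec(f"p{i}", -1.5, 0.3) for i in range(5)],
        )
        exp = expected_scores(cfg).set_index("group_id")["expected_score"]
        n_reps = 200
        estimates = {c: [] for c in exp.index}
        for rep in range(n_reps):
            cfg.seed = 10_000 + rep
            scores = score_all(generate_dataset(cfg)).set_index("group_id")
            for c in exp.index:
                estimates[c].append(scores.loc[c, "score"])
        for c in exp.index:
            est = np.asarray(estimates[c])
            se = est.std(ddof=1) / np.sqrt(n_reps)
            assert abs(est.mean() - exp[c]) < 3 * se + 1e-12


class TestWqsAndUsageGenerators:
    def test_zero_spread_standards_identical(self):
        cfg = _config(wqs_spread=0.0)
        wqs = generate_wqs(cfg)
        by_cas = {}
        for r in wqs:
            by_cas.setdefault(r.pesticide_cas, set()).add(round(r.value, 12))
        assert all(len(v) == 1 for v in by_cas.values())

    def test_wqs_seeded_reproducible(self):
        cfg = _config(seed=9)
        a = [(r.jurisdiction, r.pesticide_cas, r.value)
             for r in generate_wqs(cfg)]
        b = [(r.jurisdiction, r.pesticide_cas, r.value)
             for r in generate_wqs(cfg)]
        assert a == b

    def test_usage_years_and_positivity(self):
        recs = generate_usage(default_config(1))
        years = {r.year for r in recs}
        assert years == set(range(2010, 2022))
        assert all(r.pesticide_use >= 0 and r.agricultural_land > 0
                   for r in recs)

    def test_ground_config_is_valid_and_smaller(self):
        surf, ground = default_config(0), default_ground_config(0)
        assert sum(c.n_sites for c in ground.countries) < \
            sum(c.n_sites for c in surf.countries)
        assert ground.water_body == "ground"


class TestConfigFile:
    def test_toml_round_trip(self, tmp_path):
        path = tmp_path / "sim.toml"
        path.write_text(
            'seed = 7\npanel_coverage = 0.8\ncensor_quantile = 0.1\n'
            'lod_log10 = -2.0\n'
            '[[countries]]\ncode = "AAA"\nn_sites = 5\noffset = 0.5\n'
            '[[countries]]\ncode = "BBB"\nn_sites = 3\noffset = -0.5\n'
            '[[pesticides]]\ncas = "1912-24-9"\nbaseline_log10 = -1.0\n'
            'sigma = 0.4\n'
        )
        cfg = load_config(path)
        assert cfg.seed == 7
        assert [c.code for c in cfg.countries] == ["AAA", "BBB"]
        assert cfg.pesticides[0].sigma == 0.4
        assert len(generate_dataset(cfg)) > 0

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            _config(censor_quantile=1.5)
        with pytest.raises(ValueError):
            _config(panel_coverage=-0.1)
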