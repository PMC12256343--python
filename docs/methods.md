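# Methods

## Contamination score

The score compares a group's (country's or region's) pesticide levels with
global levels on the log10 scale. For water body w, every harmonized record
contributes one *effective log concentration*: `log10 C` for detected
site-mean concentrations, `log10 LOD` for non-detects, `log10 LOQ` when no
LOD was reported. Records offering none of the three are excluded during
harmonization, record-wise (the rest of the site is kept). Duplicate rows
for one site × pesticide are averaged on the log scale — a geometric mean
of concentrations — because all downstream arithmetic is on logs.

Per pesticide, the *central tendency* is the flat mean of effective log
concentrations over every site worldwide reporting it; each site counts
once regardless of country, which is what makes the country scores
site-weighted. Per site, deviations from the central tendencies are
averaged over the `N_m` pesticides usable at that site (`N` is per-site by
design: monitoring panels are heterogeneous, and any fixed global `N`
would either drop sites or impute values). The group score `S` is the flat
mean of site values over the group's `M` sites. A pesticide observed at a
single site globally has deviation 0 there (its tendency is itself); such
pesticides are retained by default, with a configurable minimum-site
threshold for sensitivity analyses. Detected values below their own
reported LOD are taken at face value.

Bands: `S ≤ 0` at or below the global level, `0 < S < 2` slightly higher,
`S ≥ 2` significantly higher (roughly: orders of magnitude above the
global mean). The band is a pure step function of `S`; scores are kept at
full precision in CSV output and rounded to two decimals only in printed
summaries.

Regional scoring reuses the same machinery with `country:region` group
keys. Its default reference population is `within_country` — central
tendencies from the country's own records — because the regional view asks
about internal disparities; a global reference is available by flag.

Properties the tests enforce: translation invariance (multiplying all
concentrations by a constant leaves every `S` unchanged); conservation
(with one shared fully detected panel the site-weighted sum of scores is
exactly 0); equivalence with a brute-force evaluation to 1e-12; and
monotonicity of a group's score in its own concentrations.

## Bootstrap uncertainty

The resampling unit is the sampling site — the score's atomic unit. A
group's `M` sites are drawn with replacement `B` times (default 1000) and
`S` recomputed per replicate; the CI is the percentile interval (default
95%). Global central tendencies stay fixed at full-data values so the
interval isolates within-group sampling variability; recomputing them per
replicate (including the resampled sites) is available behind a flag and
widens intervals slightly for groups that dominate a pesticide's global
site count. Groups with one site refuse to bootstrap rather than returning
a degenerate interval. BCa/jackknife intervals are out of scope.

## Regulation scores

Standards enter as (jurisdiction, pesticide, medium, value) rows, log10-
transformed. When a jurisdiction keeps several standards systems for one
medium, the most conservative system is selected: uniform dominance wins
outright, otherwise the system with the lower mean log10 value over its
regulated pesticides, with a lexical tie-break on system id for
determinism. EU member states inherit bloc-level rows for any pesticide ×
medium they do not regulate nationally, which reproduces identical scores
across members where only bloc standards exist. A system listing a
pesticide twice contributes its stricter (lower) value.

Global per-pesticide statistics (mean `μ_i`, sample standard deviation
`σ_i` with ddof = 1, min, max) are computed across the jurisdictions
regulating pesticide *i*, one value each after system selection, with the
scored jurisdiction included (no leave-one-out). `CS` counts regulated
panel pesticides; `NS1 = Σ 1 − Φ((log10 WQS − μ_i)/σ_i)`;
`NS2 = Σ clamp(1 − (log10 WQS − min_i)/(max_i − min_i))` with a neutral
0.5 term (flagged) when max = min, since dropping the term would silently
change the score ceiling; `NS3` is the mean log deviation from `μ_i` over
the `N` regulated pesticides. `NS1` additionally carries a validity flag
from a per-pesticide Shapiro–Wilk test on the log standards (α = 0.05):
if any tested pesticide rejects, the log-normal model behind `NS1` is
unsupported and the flag is false (the value is still computed for
inspection). A pooled variant of the test exists but mixes scales across
pesticides, so per-pesticide is the default. Pesticides with fewer than 3
values or zero variance are skipped with a reason.

The 30-pesticide panel is data, not code: a representative default panel
of commonly monitored pesticides ships with the package and any panel file
(one CAS per line) can be supplied.

## Usage intensity

`PUI` for a country is the mean over available years in 2010–2021 of
(tonnes applied)/(km² agricultural land). Missing years renormalize the
denominator; imputing them as zero would understate intensity. Land area
is accepted in km² or hectares (1 km² = 100 ha).

## Hazard quotients and exceedance

Countries with `S > 2` are screened with the standard chronic
drinking-water ingestion model, `CDI = (C·IR·EF·ED)/(BW·AT)` in
mg/(kg·day) and `HQ = CDI/RfD`. The exposure concentration per country ×
pesticide is the maximum detected site mean (a peak-exposure screen; the
arithmetic mean is available by flag). Defaults are the usual adult
residential factors — IR = 2 L/day, BW = 70 kg, EF = 350 days/year,
ED = 30 years, AT = ED·365 days — all configurable, and reference doses
are read from a small bundled table of published chronic oral RfDs that
any user table can replace.

Exceedance rates cover five commonly detected and regulated pesticides
(aldrin 309-00-2, dieldrin 60-57-1, 2,4-D 94-75-7, heptachlor 76-44-8,
lindane 58-89-9). Per pesticide × country, the rate is the fraction of
samples strictly above the applicable drinking-water standard — national
where one exists, otherwise the WHO guideline value; countries with
neither are excluded and reported. Non-detects count as non-exceeding at
their censoring limit unless that limit itself exceeds the standard, in
which case the record is indeterminate and excluded from both counts. The
global rate aggregates the counts, so it equals the record-count-weighted
mean of country rates. EU member states can be excluded by flag (their
drinking water is treated before use, so raw-freshwater exceedance is not
meaningful there).

## Association

Only groups present in both score sets are compared. Ranks are descending
(rank 1 = highest score) with average ranks on ties; the per-group
absolute rank difference is the consistency measure. Association reports
Spearman's rho with a two-sided p — an exact permutation p by full
enumeration for n ≤ 9, the large-sample approximation otherwise — and a
simple least-squares regression of the second set on the first (slope,
intercept, R², slope p). Significance labels (p < 0.1 correlation,
p < 0.05 regression) annotate the result and never filter it. The
"sufficient and balanced sampling" subset used in some comparisons has no
algorithmic definition, so it is accepted only as a user-supplied group
list.

## Synthetic generator

`generate_dataset` draws, per site × pesticide, a log10 concentration from
`Normal(baseline_n + δ_country, σ_n)`, includes the pair with probability
`panel_coverage`, and reports it as a non-detect at the configured LOD
with probability `censor_quantile` — censoring is an independent Bernoulli
per record, chosen so the realized non-detect fraction is binomial around
the configured value regardless of the concentration distribution. This
emulates reporting practice, not the value-dependent censoring of real
chemistry, where low values are the ones lost; with a fixed LOD the model
still reproduces the key bias direction (censoring pulls scores toward the
LOD), which the tests exercise.

With full coverage and no censoring the expected score has the closed
form `E[S_j] = δ_j − Σ_k w_k δ_k` (`w_k` = site share), exact at σ = 0;
`expected_scores` refuses configs outside that regime rather than
returning an approximation. Companion generators draw per-jurisdiction
log-normal standards tables (spread and offset configurable) and
usage/land tables whose intensity scales with the country offset.

Default scenario: ten countries with uneven networks (8–60 sites),
offsets from −2.0 to +2.6 log10 units, ten pesticides with baselines
−2.9 … −1.0 log10 μg/L and σ = 0.5–0.7, 70% panel coverage, 30%
non-detects at LOD 10⁻³ μg/L — magnitudes typical of compiled freshwater
monitoring data, including a couple of clearly elevated and clearly clean
countries. The groundwater companion halves site counts, attenuates
offsets by 0.8 and lowers baselines by 0.4. What the generator does not
emulate: spatial site placement and clustering, temporal trends,
value-dependent censoring, inter-lab LOD variation, and correlated
pesticide panels. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated sampling model, not
robustness to spatially or analytically biased real-world networks.

## Test problem sizes and numerical choices

Oracle-equivalence tests compare against independent brute-force
evaluations (pure-Python loops, `erfc`-based normal CDF, rank-then-Pearson
Spearman) at 1e-12 on ≤5-entity instances. Parameter recovery uses 200
replicates of 3 countries × 30 sites × 5 pesticides at σ = 0.3 and checks
each country's mean estimate within 3 Monte-Carlo standard errors of the
closed form. Bootstrap coverage uses 300 datasets at B = 200 with a
100-site target country against two 200-site reference countries — large
reference networks keep the fixed central tendencies close to truth, so
the percentile interval's coverage is dominated by within-country
resampling — and asserts 95% ± 3%. Quantiles use numpy's default linear
interpolation. All stochastic tests fix seeds; the acceptance script
derives every seed from its `--seed` argument.

## Known limitations

Site-representativeness is not corrected: a country sampled only at
hotspots scores high legitimately under the model. Scores are relative
indicators and carry no safety threshold; the hazard-quotient screen
exists precisely because a high `S` alone does not establish risk.
`NS1–NS3` depend on which jurisdictions happen to regulate a pesticide, so
adding a jurisdiction changes others' scores; they are comparative, not
absolute. The exceedance comparison treats site means as samples, so it
understates within-site temporal exceedance.
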