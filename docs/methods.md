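# Methods

This note documents the models and procedures implemented in `nutlim`, the
assumptions behind them, the tunable parameters, and the choices made where
the design was genuinely open.

## Harmonisation of sample records

Monitoring records arrive with mixed units, censored values and
heterogeneous analytical methods. Three screens are applied per site–analyte
series:

1. **Unit-anomaly screen.** A value at least `unit_anomaly_factor` (default
   100) times the series median is flagged `suspect_units` and excluded. The
   factor targets the common µg-recorded-as-mg error (×1000) while being
   insensitive to genuine enrichment episodes (rarely >100× the median at
   baseflow). Flagged rows are excluded, never corrected: an automated
   pipeline has no basis for inventing a corrected value, so exclusion with
   a logged reason is the only defensible action. Single-sample series have
   no reference median and are never flagged.
2. **Censored values.** Left-censored observations (below the detection
   limit, DL) are substituted at 0.5 × DL. If more than 10% of a series is
   censored the whole series is excluded (`too_censored`) — substitution at
   that density would visibly distort a median. Exactly 10% is retained
   (the rule is strictly "more than"). The censored fraction is evaluated on
   the analysis window, i.e. after the baseflow/date/season filters, since
   the exclusion rule is a property of the data actually summarised. We use
   substitution rather than Kaplan–Meier or MLE censored estimators because
   the downstream statistic is a median with censoring capped at 10%, where
   substitution at DL/2 is unbiased for the median unless censoring reaches
   the median itself.
3. **Method acceptance.** TN/TP are kept only from strong-acid or
   acidified-persulfate digestion of unfiltered samples; DRP only when
   filtered strictly below 0.7 µm (0.45 µm filters qualify; 0.7 µm exactly
   does not); nitrate from ion chromatography, cadmium reduction, azo-dye
   colorimetry or optical sensors. Unknown codes are rejected with a logged
   reason, not an exception — method vocabulary varies across databases and
   a single stray code must not abort a run.

## Baseflow separation and the 75% rule

Periphyton is scoured by storm flows, and storm-water chemistry does not
reflect growing-condition concentrations, so samples are restricted to
baseflow-dominated days. Daily discharge is separated with the Lyne–Hollick
single-parameter recursive filter: per pass,

    qf_t = α qf_{t−1} + ((1+α)/2)(Q_t − Q_{t−1}),  qf clamped to [0, Q_t],
    baseflow = Q − qf,

with the baseflow of each pass feeding the next and passes alternating
forward/backward. Defaults are the conventional daily-data values
α = 0.925 and 3 passes; both are config-exposed because they are
conventions, not identified constants. Series are padded by reflecting 30
days at each end so the recursion warms up outside the reported span. Gaps
in the record split the series into independently filtered segments;
segments shorter than 10 days stay unfiltered (too short for the recursion
to stabilise) and their days drop out with reason `no_flow_record`.

A sample is retained when the baseflow share of its sampling day's flow is
at least 0.75 (inclusive). The criterion is evaluated on the sampling day
itself, not an antecedent window — the day's flow composition is what
determines whether the sample chemistry is baseflow chemistry. Zero-flow
days have baseflow fraction 1 by convention (no quickflow is possible).
Sites pair with a gauge no more than 50 km downstream (inclusive); nearer
gauges win ties, and unpaired sites leave the analysis with reason
`no_gauge`.

## Windows, seasons, eligibility, medians

Analysis is restricted to 1990–2016 and, per site–analyte, to the most
recent seven years of its record (anchored at its last in-range sample);
this bounds drift from land-use and climate trends while keeping enough
samples for a stable median. Growing-season months are May–October above
the Tropic of Cancer and November–April below Capricorn; within ±23.43695°
all months count. A series is eligible when it retains ≥37 samples with a
median inter-sample gap ≤61 days — the operationalisation chosen for
"sampled at least once every two months", which no closed formula defines;
the median gap tolerates the regular long gap that seasonal truncation
introduces between years while still rejecting quarterly schedules (~91-day
gaps). Medians are the standard middle-value statistic. Catchments with
several eligible sites take the median of site medians: with two-stage
sampling of unknown within-catchment design, the median of per-site
summaries is the pooling rule robust to unequal site record lengths.

Because the seven-year window is anchored on the series' own last retained
date, the window filter is not a pure row-wise predicate; the pipeline
therefore fixes the order baseflow → window → season. Season and baseflow
filters are row-wise and commute freely.

## Regression in log space

Concentration medians are right-skewed; models are fit to natural-log
medians (Shapiro–Wilk statistics for raw and logged responses are reported,
and a warning is logged if the logged response still rejects normality at
p < 0.05 — the fit proceeds, since OLS point estimates do not require
normality). Continuous predictors enter as catchment means; categorical
predictors expand to indicator blocks (reference level = most frequent
category) that enter and leave the subset search together, because a factor
is either in the model or not.

Subsets are scored with Mallows Cp = SSE_p/σ̂²_full − n + 2p, with σ̂²_full
from the model containing every candidate predictor; the full model
satisfies Cp = p identically, which the tests assert on every fitted
dataset. All 2^k block subsets are enumerated for k ≤ `max_exhaustive`
(default 20; subset SSEs come from Gram-submatrix solves, so enumeration is
cheap); larger pools are first capped by a greedy forward pre-screen. The
default choice minimises Cp, with ties broken toward fewer parameters and
then lexicographic names; the more parsimonious "smallest p with Cp ≤ p"
rule is available as `selection_rule = "cp_le_p"`. Per-coefficient t-tests
are reported at P < 0.05 but never drive selection.

Back-transformed predictions are corrected with Duan's smearing factor
S = (1/n) Σ exp(ε̂ᵢ), the nonparametric retransformation-bias correction;
S ≥ 1 whenever residuals are centred (Jensen), S = 1 for a perfect fit, and
S is applied uniformly across predictions under the homoscedasticity
assumption (no weighted variant is provided). Hold-out validation reports
the squared correlation between log observed and log predicted (so
validating on the training set reproduces the training R² exactly), the
observed-on-predicted slope, and percent bias on the concentration scale.

**On "recovery" of the true predictor set.** Minimising Cp admits a noise
predictor whenever its partial t² exceeds 2 — about a 16% event per noise
column — so no correct Cp implementation selects *exactly* the true set
with high probability. Recovery is therefore scored as: every truly active
predictor selected, with its coefficient within 3 standard errors of truth.
False inclusions are visible in the reported subset and Cp table but are
the selection rule's documented behaviour, not an error.

## Thresholds and classification

The literature survey of periphyton nutrient thresholds is summarised per
analyte (arithmetic mean, SE = sd/√n, range), and a one-way ANOVA across
biomes (F and p, with the between/within sum-of-squares decomposition
reported) checks whether biome-specific thresholds are warranted; with no
detectable biome differences, the global means are used. Dissolved-nutrient
(DRP, NO3-N) thresholds are summarised for completeness but not used in
classification.

Classification crosses the limiting nutrient with its enrichment status:
mass N:P < 7 means N-limited, ≥ 7 P-limited; the limiting nutrient's median
above its threshold (TN 0.800, TP 0.046 mg L⁻¹) means undesirable growth.
Types: 1 = N/acceptable, 2 = N/undesirable, 3 = P/acceptable,
4 = P/undesirable. Two boundary conventions are fixed and configurable:
a median exactly at its threshold is "acceptable" (the source rules use
strict inequalities on both sides, leaving equality undefined; acceptable
is the conservative reading), and a computed ratio within a relative 1e-9
of the boundary is treated as exactly at it, so quotients like 0.70/0.100
(one ulp below 7) take the P-limited branch. One published table caption
gives the TP threshold as 48 µg L⁻¹ where the methods and figure captions
give 46; the package fixes 0.046 mg L⁻¹ and treats 48 as a typographical
inconsistency. Regional rule sets (e.g. US ecoregion thresholds) can
replace the global thresholds per region, with a difference report of area
per type under both rule sets; regions with only one of the two thresholds
are an error, and catchments without a region either fall back to the
global rule or are excluded, per configuration.

## Aggregation

Sums of area, population and land use are taken over (continent, type) and
world cells on unrounded values; rounding to reporting precision (0.1 M
km²) happens only in the rendering helper, because rounded continental
cells do not generally re-sum to a rounded world row. Percentages within a
grouping are computed from unrounded areas and may sum to 100 ± rounding.
The world row excludes configured regions (default Antarctica and
Greenland). Headline shares: undesirable = (type 2 + type 4) area over
classified area; N/P shares split the undesirable area by limiting
nutrient.

## Synthetic data generator

The generator emulates the structure of a global monitoring compilation at
toy scale so every stage runs against known truth:

- **Hydrographs** — a baseflow store relaxing toward its base level
  (recession rate 0.05 d⁻¹) plus Bernoulli storm pulses (default 0.08 d⁻¹,
  exponential magnitudes of mean 10× base level) split 90% to quickflow
  (two-day decay half-life) and 10% to baseflow recharge. The recharge
  split was fixed by pilot runs: it keeps the generated baseflow share
  within the recursive filter's resolving power (|filter BFI − true BFI|
  < 0.1 across seeds) while still producing storm days that the 75% rule
  excludes.
- **Samples** — log-normal concentrations around each site's true log
  median (site offset sd = the catchment residual sd, default 0.3; sample
  sd 0.5), on a fortnightly schedule over 5 years. Fortnightly is the
  deliberate default: a temperate site's growing season yields at most six
  months of samples per year, so a monthly schedule cannot reach the
  37-sample eligibility minimum within a seven-year window; fortnightly
  sampling leaves realistic eligibility pressure (some sites still fail)
  without emptying the pipeline. Detection limits sit at each series' own
  `censor_target` quantile, so realised censoring concentrates at the
  target. Latitudes span −45° to 60°, populating both hemispheres and the
  tropics.
- **Catchments** — standard-normal continuous predictors, a five-level
  biome factor (inactive in the truth), sparse truth β (first `n_active`
  predictors, alternating sign), log-uniform areas (10²–10⁵ km²),
  populations tracking the first predictor, Dirichlet land-use splits.
  Default intercepts put geometric-mean medians at ~0.6 (TN) and ~0.04
  (TP) mg L⁻¹, realistic mid-range river concentrations that straddle the
  classification thresholds.
- **Threshold survey** — 27 studies, log-normal around the global analyte
  means (cv 0.5, mean-corrected so the arithmetic mean equals the target),
  with biome labels of equal means so the ANOVA rejects at ≈ the nominal
  rate.

All generators are pure functions of (parameters, seed).

What passing on this synthetic world does **not** show: real monitoring
data have spatially correlated predictors, non-stationary and serially
correlated concentration series, heteroscedastic residuals, reporting-limit
changes over time, and rating-curve errors in discharge. The generator has
none of these, so the tests certify the pipeline's logic and its behaviour
under its own stated model, not performance on field data.

## Problem sizes and numerical choices

The recovery suite uses 100 synthetic worlds of 500 catchments with 2
active of 10 continuous predictors at residual sd 0.3 — large enough that
the 3-SE coefficient criterion has near-nominal coverage, small enough that
the whole suite runs in well under a minute. Subset SSEs are computed from
the precomputed Gram matrix (solve per subset); the final fit goes through
statsmodels OLS, and the two routes are cross-checked against a
normal-equations oracle in the tests. Rank deficiency is detected by QR
diagnostics and reported with the offending columns. Degenerate inputs with
defined behaviour: single-sample series (never anomaly-flagged), zero-flow
days (baseflow fraction 1), all-equal responses (normality undefined,
warned), empty catchments (absent from output).

## Known limitations

- The filter parameterisation (α, passes, 75% day rule) is a convention;
  the package makes it explicit config rather than claiming an identified
  value.
- Substitution-based censoring handling breaks down above the 10% cap by
  design; heavily censored networks need ML/KM estimators (out of scope).
- No spatial autocorrelation or mixed-effects structure in the regression;
  catchments are treated as exchangeable given predictors.
- Classification ignores N-fixing cyanobacteria, which can overcome
  N-limitation and make type-1 assessments optimistic.
- GIS operations (rasterisation, basin geometry, mapping) are out of scope;
  catchment identities, areas and predictor summaries are inputs.
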