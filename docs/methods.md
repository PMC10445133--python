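# Methods

## Analysis model

The estimand is the pre/post change in the odds that a pruritus alert is
followed by a clinic visit within a 4-week window. The study design is
observational: two consecutive 292-day periods (584 days total), with
the alert-generating algorithm applied identically in both, but alerts
visible to owners only in the second. Period 2 therefore plays the role
of exposure and period 1 of control, and all confounding that is stable
across periods (dog, owner, clinic propensity) cancels only to the
extent the periods are exchangeable — the package makes no attempt to
adjust for secular trends, which is a limitation of the design itself.

### Severity levels and sufficiency

Daily totals (scratch seconds/day, lick minutes/day) are smoothed with a
trailing 7-day rolling mean taken over days with wear fraction > 0;
no-wear days are excluded from the mean rather than imputed as zeros.
The printed level bands leave boundary values ambiguous (the scratch
bands skip (299, 300] and the lick bands reuse 7, 19, 43 at both ends),
so the package adopts one consistent convention: lower-inclusive,
upper-exclusive bins with cut points 53/120/300 s/day and 7/19/43
min/day. Rolling means are fractional, so integer-band literalism is
not possible anyway. Data sufficiency is the sum of the window's wear
fractions ≥ 3.5 days — a fractional-wear reading of the "3.5 days in
the previous 7" rule; exactly 3.5 qualifies.

The rolling window is the current day plus the previous six. Whether
the deployed system excluded the current day is not documented; the
trailing-window-including-today convention is a package decision and is
exercised consistently by the alert engine and all tests.

### Alert engine

An alert fires on a dog-day when the scratch or lick level exceeds the
level on the comparison day. The comparison day is the most recent
prior day with sufficiency, looked back at most 7 days; a longer gap
yields no alert, which approximates re-establishing a baseline after
long non-wear gaps. Both days must be sufficient. No alert may fire
before day 9 of usage (the first 8 calendar days after the first worn
day are ineligible), reflecting the 7-day start-up baseline. A
simultaneous rise in both metrics emits a single alert with trigger
`both` — this makes the total alert count identical whether alerts are
tabulated by scratch level or by lick level, matching the published
accounting. There is no cooldown: consecutive-day rises each alert.

### Attribution

Matching is greedy, chronological, and one-to-one per dog: each alert
consumes the earliest not-yet-matched visit at lag 0–28 days. Lag 0
(same-day visit) counts as within-window, week bin 1; week bins are
lags 0–7, 8–14, 15–21, 22–28 (bin = ⌈max(lag,1)/7⌉). The one-to-one
reading of the "multiple alerts / multiple visits" rule is adopted
because the published alert-side and visit-side totals coincide.
Matching runs over the whole study span, so an alert late in period 1
may be discharged by a visit dated early in period 2; 2×2 tables
classify the pair by the alert's period, visit-side tables by the
visit's period. Dermatitis subgroups count only first-period visits
with a dermatitis outcome (0 / 1 / 2–5 / ≥6 → groups 0–3); dogs with no
first-period visits are group 0.

### Odds ratios

For each stratum, OR = (a/b)/(c/d) with SE(ln OR) = √(1/a+1/b+1/c+1/d),
95% CI = exp(ln OR ± 1.96·SE), z = ln OR / SE, two-tailed normal p.
If any single cell is zero the Haldane–Anscombe 0.5 correction is added
to all four cells (never triggered by the published tables); a wholly
empty row or column raises an undefined-estimate error. Reports print
ORs to 2 d.p. (4 d.p. for the combined table), CIs to 2 d.p., and
p-values below 10⁻⁴ as "<0.0001"; machine output keeps full precision.
Two of the published CI bounds (occasional-scratching lower bound,
severe-licking upper bound) differ in the last printed digit from what
these formulas produce; the package reports the formula values.

### Eligibility

A dog enters a period's analysis only with at least one alert and at
least one clinic visit in that period (`eligibility="visit_and_alert"`,
the source study's rule). For simulation experiments an
`alert_only` mode drops the visit requirement, because conditioning on
the outcome (a visit) distorts a configured per-alert response
probability.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
defaults describe a cohort resembling the source study's conditions.

| parameter | default | meaning |
|---|---|---|
| n_dogs | 1000 | cohort size (demo scale) |
| period_length_days × n_periods | 292 × 2 | the 584-day pre/post design |
| baseline_scratch_mean | 80 s/day | typical rolling level in the occasional band |
| baseline_lick_mean | 12 min/day | likewise |
| scratch_shape / lick_shape | 4 | gamma shape of daily totals (right-skewed) |
| flare_rate | 3 /dog/period | episodic pruritic flares (Poisson) |
| flare_magnitude | 3× | multiplicative uplift on flare days |
| flare_duration_days | 7 | flare length |
| wear_prob | 0.9 | probability of a full-wear day |
| partial_wear_fraction_range | (0.3, 1.0) | uniform partial wear otherwise |
| baseline_visit_rate | 2 /dog/period | clinic-visit propensity (Poisson, uniform dates) |
| response_prob_pre / post | 0.0 / 0.03 | per-alert induced-visit probability |
| dermatitis_outcome_prob | 0.5 | dermatitis flag on induced visits |
| baseline_dermatitis_prob | 0.3 | dermatitis flag on baseline visits |
| prescriptions_per_visit | 0.7 | Poisson treatment courses per visit |

Daily behavior is i.i.d. gamma around the baseline mean (shape 4 keeps
the 7-day rolling mean variable enough to cross level cuts at a
realistic rate — roughly 10 alerts per dog per period at defaults, in
the neighborhood of the source cohort's burden), multiplied by the
flare uplift on flare days. Behavior is recorded at its full daily
value whenever wear > 0; wear only gates sufficiency. The owner
response is mechanistic and honest to the analysis: the generator runs
the package's own alert engine on the simulated telemetry, then each
alert independently induces a visit at a uniform 0–28-day lag with the
period's response probability, clipped to the study end so the
configured probability is realized exactly. `response_prob_pre` is 0
by default because period-1 owners could not see alerts. Drug names
are sampled from the five-category dermatologic catalog with fixed
weights (0.35/0.25/0.20/0.12/0.08 for antipruritic/antibiotic/otic/
topical-skin/nutritional).

What the generator does **not** emulate: within-day behavior structure
(the lag-to-visit law and flare placement are simulator choices, as no
law is published), between-dog frailty in behavior or visit propensity,
demographics, seasonality, or the pandemic-era visit decline. Passing
tests therefore demonstrate correctness of the *pipeline* under the
assumed data-generating process, not fidelity of any particular real
cohort.

Dual-listed drugs (e.g. gentamicin/betamethasone, listed as both an
antibiotic and an otic preparation) classify by the prescription's
context field when given, else by the fixed priority otic >
topical_skin > antibiotic.

## Validation experiments

**Published-counts analysis.** The printed 2×2 counts and totals ship
as package data; the statistics stage reproduces every published odds
ratio, CI bound, fraction, and per-dog mean exactly at printed rounding
(subject to the two last-digit CI discrepancies noted above). This
separates exact numeric verification from stochastic pipeline tests.

**Oracle equivalence.** On cohorts of ≤50 dogs × 60 days, the
vectorised alert engine is compared alert-for-alert against an
independent plain-Python day-by-day recomputation of all rules.

**CI coverage.** 500 2×2 tables drawn from binomials at the published
per-alert match probabilities (4.74% / 7.49%, 10,000 alerts per arm)
give empirical 95%-CI coverage within 92–98%.

**Parameter recovery.** A 5,000-dog cohort (scaled down from the
source cohort's 8,631) is simulated with no baseline visit propensity
and response probabilities 0.20 / 0.28908, so every match traces back
to the owner-response mechanism and the configured per-alert odds ratio
is 1.6265. The probabilities are larger than the source cohort's
per-alert fractions to keep the estimator well powered at the reduced
cohort size. The pipeline's estimand is not exactly the configured
odds ratio: greedy one-to-one matching lets an unmatched period-1 alert
near the period boundary consume a period-2 induced visit, attenuating
the estimate slightly. The procedure-implied large-sample value under
this design, computed once from 60 independent replicates of 2,000 dogs,
is 1.5775 (Monte Carlo SE ≈ 0.009); the acceptance test checks that a
single 5,000-dog run's CI covers this implied value and that the
estimate lies within ±0.15 of the configured 1.6265.

## Problem sizes and numerical conventions

Test and acceptance runs use 25–1,000-dog cohorts (5,000 for the
recovery experiment); the full pipeline on 1,000 dogs × 584 days runs
in seconds and is byte-reproducible under a fixed seed (all randomness
flows from one `numpy` `default_rng`). Rolling statistics use exact
cumulative sums (no floating drift at these scales); level assignment
uses `searchsorted` with lower-inclusive bins; dates are handled as
calendar days throughout (no time-of-day). Degenerate inputs (no wear,
empty strata, zero cells, empty eligible sets) are either well-defined
(no alerts, zero counts) or raise typed errors naming the offending
field.

## Known limitations

* The pre/post contrast carries all limitations of the original
  design: no causal identification, no adjustment for secular trends.
* The simulator's i.i.d. gamma behavior lacks the heavy between-dog
  skew of the real alert distribution (mean ≫ median in the source
  cohort); per-dog frailty would be the natural extension.
* The boundary attenuation of the matching procedure (above) is a
  property of the published method itself; the package documents it
  rather than redefining the method.
* Telemedicine visits, notification delivery, and diagnosis-code
  mapping are out of scope; dermatitis outcomes are a boolean flag.
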