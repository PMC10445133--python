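# pruralert

Pruritus (itch) is the most common clinical sign in small-animal
dermatology, and dog owners often cannot tell normal scratching from
abnormal. Collar-mounted accelerometers paired with behavior-recognition
analytics can quantify a dog's daily scratching (seconds/day) and
self-licking (minutes/day) and push a **pruritus alert** to the owner
when the behavior level rises. `pruralert` implements, as a tested and
fully reproducible pipeline, the computational core of a retrospective
pre/post evaluation of such alerts:

1. **Rolling severity levels.** Each dog-day's 7-day trailing rolling
   averages of scratching and licking are binned into four ordered
   levels — infrequent `[0, 53)` s/day (lick `[0, 7)` min/day),
   occasional `[53, 120)` (`[7, 19)`), elevated `[120, 300)`
   (`[19, 43)`), severe `[300, ∞)` (`[43, ∞)`). Days without collar
   wear are excluded from the mean; a day's levels count only when the
   window's wear fractions sum to ≥ 3.5 days.
2. **Alert engine.** An alert fires when either level rises by ≥ 1
   category versus the most recent sufficient prior day (looking back at
   most 7 days), no earlier than day 9 of collar usage (a 7-day baseline
   must precede any alert). Simultaneous scratch+lick rises emit one
   alert with trigger `both`.
3. **Attribution.** Each alert is paired, greedily and one-to-one, with
   the first not-yet-matched clinic visit within 28 days ("alert
   visit"); matches are binned by week of lag. Dogs are stratified into
   dermatitis subgroups (0 / 1 / 2–5 / ≥ 6 first-period visits with a
   dermatitis outcome → groups 0–3) and prescriptions are flagged when
   their visit falls within 28 days after any alert.
4. **Statistics.** The study span splits into two consecutive 292-day
   periods; alerts were visible to owners only in the second. For each
   stratum the 2×2 table of matched/unmatched alerts by period yields
   the log-method odds ratio

   ```
   OR = (a/b)/(c/d),   SE(ln OR) = √(1/a + 1/b + 1/c + 1/d)
   95% CI = exp(ln OR ± 1.96·SE),   z = ln OR / SE  (two-tailed)
   ```

   with the Haldane–Anscombe 0.5 correction when a single cell is zero.

Because the source cohort's raw telemetry is not deposited, a
**synthetic-cohort generator** emulates it — gamma-distributed daily
behavior with episodic flares, partial collar wear, baseline clinic
visits, and a configurable owner-response model in which each alert
induces an extra visit within 28 days with a period-specific
probability — so every stage runs with no download. The published
summary counts are additionally bundled as package data, making the
statistics stage exactly checkable against the printed results.

The package is aimed at biostatisticians and veterinary-informatics
researchers who want to re-run, stress-test, or extend this style of
exposure-window pre/post analysis.

## Worked example

```python
from pruralert import AlertResponseModel, CohortConfig

config = CohortConfig(n_dogs=500, response_prob_post=0.10, rng_seed=7)
results = AlertResponseModel.from_simulation(config).fit()
print(results.summary())
```

```
Alert-visit odds-ratio analysis (period 2 vs period 1)
========================================================
period 1: 426 dogs, 4510 alerts (mean 10.6/dog, median 10.0, max 24)
period 2: 479 dogs, 5351 alerts (mean 11.2/dog, median 11.0, max 23)
--------------------------------------------------------
stratum                     OR          95% CI         p
scratch/infrequent        1.57      0.24-10.22    0.6361
scratch/occasional        2.08       1.79-2.42   <0.0001
scratch/elevated          1.96       1.64-2.34   <0.0001
scratch/severe            1.03       0.36-2.92    0.9578
lick/infrequent           2.44      0.41-14.75    0.3297
lick/occasional           1.98       1.73-2.28   <0.0001
lick/elevated             2.14       1.74-2.63   <0.0001
lick/severe               1.55       0.64-3.73    0.3278
combined                1.9929       1.78-2.23   <0.0001
--------------------------------------------------------
period 1: alert visits = 11.35% of alerts, 50.8% of visits
period 2: alert visits = 20.33% of alerts, 71.4% of visits
period 1: 52.6% of 717 medications within 28 days of an alert
period 2: 74.4% of 1040 medications within 28 days of an alert
```

Here 500 dogs were simulated over 2×292 days with owners responding to
10% of period-2 alerts and to none in period 1. The combined odds ratio
(~2.0, CI 1.78–2.23) says an alert was twice as likely to be followed by
a 4-week clinic visit in the period when owners could see alerts; the
per-stratum rows repeat the comparison at each severity level at alert
time (sparse strata have wide CIs). The percentages give the alert-side
and visit-side views of the same matching, and the medication lines the
share of prescriptions written within the 28-day post-alert window.

The same analysis is available from the shell:

```bash
pruralert all --seed 7 --out run/           # simulate → … → report
pruralert report --reference-counts         # published-counts analysis
```

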