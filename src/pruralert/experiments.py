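"""Designed simulation experiments: parameter recovery and CI calibration.

Two reusable experiments validate the estimation machinery end to end:

* :func:`recovery_experiment` simulates a full cohort with a configured
  owner-response uplift whose naive per-alert odds ratio is ~1.63, runs
  the whole pipeline, and returns the estimated overall odds ratio.
  Because the greedy one-to-one matching lets an unmatched period-1
  alert near the period boundary consume a period-2 induced visit, the
  procedure's large-sample limit sits slightly below the configured
  odds ratio; the implied (procedure-level) value for this design was
  computed once from a 60-replicate simulation and is exposed as
  ``RECOVERY_IMPLIED_OR``.

* :func:`ci_coverage_experiment` draws many 2x2 tables from binomial
  sampling at fixed per-alert visit probabilities and measures how
  often the log-method 95% CI contains the true odds ratio.
"""

from __future__ import annotations

import numpy as np

from .config import CohortConfig
from .model import AlertResponseModel
from .stats import TwoByTwoTable, odds_ratio

__all__ = [
    "RECOVERY_CONFIG",
    "RECOVERY_TRUE_OR",
    "RECOVERY_IMPLIED_OR",
    "recovery_experiment",
    "ci_coverage_experiment",
]

# Recovery design: no baseline visit propensity, so every matched visit
# traces back to the owner-response mechanism and the per-alert match
# probability equals the configured response probability.  Response
# probabilities 0.20 / 0.28908 give odds(0.28908)/odds(0.20) = 1.6265.
# Sparse alerting (high gamma shape, one flare per period) keeps the
# boundary interaction between periods small.
RECOVERY_CONFIG = dict(
    baseline_visit_rate=0.0,
    response_prob_pre=0.20,
    response_prob_post=0.28908,
    scratch_shape=8.0,
    lick_shape=8.0,
    flare_rate=1.0,
    flare_magnitude=4.0,
    prescriptions_per_visit=0.0,
)

_r1 = RECOVERY_CONFIG["response_prob_pre"]
_r2 = RECOVERY_CONFIG["response_prob_post"]

#: odds ratio implied directly by the configured response probabilities
RECOVERY_TRUE_OR = (_r2 / (1 - _r2)) / (_r1 / (1 - _r1))

#: large-sample limit of the pipeline estimator under RECOVERY_CONFIG
#: (mean over 60 independent replicates of 2,000 dogs; Monte Carlo
#: standard error ~0.008), slightly below RECOVERY_TRUE_OR because of
#: the period-boundary matching interaction described in the module
#: docstring and docs/methods.md
RECOVERY_IMPLIED_OR = 1.5775


def recovery_experiment(n_dogs: int = 5000, seed: int = 1) -> dict:
    """Estimate the overall odds ratio on one recovery-design cohort.

    Returns a dict with the configured truth, the implied
    (procedure-level) truth, the estimate, and its 95% CI.
    """
    cfg = CohortConfig(n_dogs=n_dogs, rng_seed=int(seed), **RECOVERY_CONFIG)
    res = AlertResponseModel.from_simulation(cfg, eligibility="alert_only").fit()
    r = res.combined_result
    return {
        "true_or": RECOVERY_TRUE_OR,
        "implied_or": RECOVERY_IMPLIED_OR,
        "estimate": r.odds_ratio,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "n_dogs": n_dogs,
        "n_alerts": len(res.alerts),
    }


def ci_coverage_experiment(
    n_draws: int = 500,
    seed: int = 0,
    p_pre: float = 0.0474,
    p_post: float = 0.0749,
    n_pre: int = 10000,
    n_post: int = 10000,
) -> dict:
    """Empirical 95%-CI coverage over repeated 2x2 binomial draws.

    Each draw samples the matched-alert counts of both periods from
    binomials at the given per-alert visit probabilities (defaults: the
    per-alert alert-visit fractions observed in the source cohort) and
    checks whether the log-method CI contains the true odds ratio.
    """
    rng = np.random.default_rng(seed)
    true_or = (p_post / (1 - p_post)) / (p_pre / (1 - p_pre))
    covered = 0
    for _ in range(n_draws):
        a = int(rng.binomial(n_post, p_post))
        c = int(rng.binomial(n_pre, p_pre))
        r = odds_ratio(TwoByTwoTable(a, n_post - a, c, n_pre - c))
        covered += r.ci_low <= true_or <= r.ci_high
    return {
        "true_or": true_or,
        "n_draws": n_draws,
        "coverage_pct": 100.0 * covered / n_draws,
    }
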