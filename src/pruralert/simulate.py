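"""Synthetic monitoring-cohort generator.

Emulates the data a collar-mounted activity monitor plus clinic EHR
system would produce for a cohort of dogs followed over two consecutive
observation periods:

* daily scratch seconds and lick minutes drawn from right-skewed gamma
  distributions around configurable baselines, multiplied by a flare
  uplift during episodic pruritic flares (Poisson number of flares per
  dog per period, fixed duration each);
* collar wear: a day is full-wear with probability ``wear_prob``, else
  a partial fraction drawn uniformly from a configured interval; days
  with zero wear record zero behavior;
* baseline clinic visits at a Poisson rate per dog per period, each
  carrying a dermatitis outcome flag with configurable probability;
* an owner-response model: the package's own alert engine is run on the
  simulated telemetry, and each alert independently induces an extra
  clinic visit at a uniform 0-28 day lag with probability
  ``response_prob_pre`` (period 1) or ``response_prob_post`` (period 2);
  induced visit dates are clipped to the study end;
* prescriptions per visit (Poisson), drawn from the dermatologic drug
  catalog with fixed category weights.

Identical configurations (including the seed) reproduce identical
tables.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .alerts import generate_alerts
from .behavior import compute_timeline
from .config import CohortConfig
from .drugs import DRUG_CATALOG, classify_drug

__all__ = ["simulate_cohort", "simulate_behavior", "write_cohort", "read_cohort"]

# Mix of treatment courses across categories, loosely matching the
# prescribing pattern of a dermatology-focused primary-care caseload.
_CATEGORY_WEIGHTS = {
    "antipruritic": 0.35,
    "antibiotic": 0.25,
    "otic": 0.20,
    "topical_skin": 0.12,
    "nutritional": 0.08,
}


def _dog_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"dog{i:0{width}d}" for i in range(1, n + 1)])


def simulate_behavior(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily behavior table (dog_id, date, scratch_seconds, lick_minutes, wear_fraction)."""
    n, days = config.n_dogs, config.n_days
    shape = (n, days)

    full = rng.random(shape) < config.wear_prob
    lo, hi = config.partial_wear_fraction_range
    wear = np.where(full, 1.0, rng.uniform(lo, hi, shape))

    flare = np.zeros(shape, dtype=bool)
    n_flares = rng.poisson(config.flare_rate, (n, config.n_periods))
    for p in range(config.n_periods):
        p0 = p * config.period_length_days
        for dog in range(n):
            k = n_flares[dog, p]
            if k == 0:
                continue
            starts = rng.integers(0, config.period_length_days, k)
            for s in starts:
                flare[dog, p0 + s : p0 + s + config.flare_duration_days] = True

    scratch = rng.gamma(config.scratch_shape,
                        config.baseline_scratch_mean / config.scratch_shape, shape)
    lick = rng.gamma(config.lick_shape, config.baseline_lick_mean / config.lick_shape, shape)
    uplift = np.where(flare, config.flare_magnitude, 1.0)
    scratch *= uplift
    lick *= uplift

    no_wear = wear <= 0
    scratch[no_wear] = 0.0
    lick[no_wear] = 0.0
    wear[no_wear] = 0.0

    grid = pd.date_range(config.period_start, periods=days, freq="D")
    return pd.DataFrame(
        {
            "dog_id": np.repeat(_dog_ids(n), days),
            "date": np.tile(grid.to_numpy(), n),
            "scratch_seconds": scratch.ravel(),
            "lick_minutes": lick.ravel(),
            "wear_fraction": wear.ravel(),
        }
    )


def _simulate_visits(
    config: CohortConfig, alerts: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    ids = _dog_ids(config.n_dogs)
    start = pd.Timestamp(config.period_start)
    rows = []

    # Baseline clinic-visit propensity, uniform within each period.
    counts = rng.poisson(config.baseline_visit_rate, (config.n_dogs, config.n_periods))
    for p in range(config.n_periods):
        p0 = p * config.period_length_days
        for dog in range(config.n_dogs):
            k = counts[dog, p]
            if k == 0:
                continue
            offsets = rng.integers(0, config.period_length_days, k)
            derm = rng.random(k) < config.baseline_dermatitis_prob
            for off, dz in zip(offsets, derm):
                rows.append((ids[dog], int(p0 + off), bool(dz), False))

    # Owner response: each alert may induce one extra visit within 28 days.
    if len(alerts):
        probs = np.where(
            alerts["period"].to_numpy() == 1, config.response_prob_pre, config.response_prob_post
        )
        respond = rng.random(len(alerts)) < probs
        lags = rng.integers(0, 29, len(alerts))
        derm = rng.random(len(alerts)) < config.dermatitis_outcome_prob
        alert_offsets = (pd.to_datetime(alerts["date"]) - start).dt.days.to_numpy()
        max_off = config.n_days - 1
        for dog, a_off, lag, hit, dz in zip(
            alerts["dog_id"], alert_offsets, lags, respond, derm
        ):
            if hit:
                rows.append((dog, int(min(a_off + lag, max_off)), bool(dz), True))

    visits = pd.DataFrame(rows, columns=["dog_id", "offset", "dermatitis_outcome", "induced"])
    visits["date"] = start + pd.to_timedelta(visits["offset"], unit="D")
    visits = visits.sort_values(
        ["dog_id", "date", "induced"], kind="stable"
    ).reset_index(drop=True)
    visits.insert(0, "visit_id", np.arange(len(visits)))
    return visits[["visit_id", "dog_id", "date", "dermatitis_outcome", "induced"]]


def _simulate_prescriptions(
    config: CohortConfig, visits: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    categories = list(_CATEGORY_WEIGHTS)
    weights = np.array([_CATEGORY_WEIGHTS[c] for c in categories])
    weights = weights / weights.sum()
    rows = []
    n_rx = rng.poisson(config.prescriptions_per_visit, len(visits))
    for vid, k in zip(visits["visit_id"], n_rx):
        for _ in range(k):
            cat = categories[rng.choice(len(categories), p=weights)]
            drug = DRUG_CATALOG[cat][rng.integers(0, len(DRUG_CATALOG[cat]))]
            rows.append((vid, drug, classify_drug(drug, context=cat)))
    rx = pd.DataFrame(rows, columns=["visit_id", "drug_name", "category"])
    rx.insert(0, "prescription_id", np.arange(len(rx)))
    return rx


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (behavior, visits, prescriptions) tables.

    The alert engine itself decides where owner-response visits can be
    induced, so the configured response probabilities act per actually
    triggered alert.
    """
    rng = np.random.default_rng(config.rng_seed)
    behavior = simulate_behavior(config, rng)
    timeline = compute_timeline(behavior)
    alerts = generate_alerts(
        timeline,
        period_start=config.period_start,
        period_length_days=config.period_length_days,
        n_periods=config.n_periods,
    )
    visits = _simulate_visits(config, alerts, rng)
    prescriptions = _simulate_prescriptions(config, visits, rng)
    return behavior, visits, prescriptions


def write_cohort(out_dir, behavior, visits, prescriptions) -> dict[str, Path]:
    """Write the three cohort tables as CSV (ISO dates); returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("behavior", behavior),
        ("visits", visits),
        ("prescriptions", prescriptions),
    ):
        df = df.copy()
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"]).dt.date
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read cohort tables written by :func:`write_cohort`."""
    d = Path(in_dir)
    behavior = pd.read_csv(d / "behavior.csv", parse_dates=["date"])
    visits = pd.read_csv(d / "visits.csv", parse_dates=["date"])
    prescriptions = pd.read_csv(d / "prescriptions.csv")
    return behavior, visits, prescriptions
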