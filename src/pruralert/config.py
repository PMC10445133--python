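"""Cohort/study configuration.

A :class:`CohortConfig` fixes both the study design (two consecutive
292-day observation periods by default) and the stochastic model of the
synthetic cohort: daily scratch/lick behavior, episodic flares, collar
wear, baseline clinic-visit propensity, and the owner-response model
(the probability that an alert induces a clinic visit within 28 days,
allowed to differ between the two periods).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass

import yaml

from .exceptions import ConfigurationError

__all__ = ["CohortConfig", "period_of_dates"]


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value)
    raise ConfigurationError(f"period_start: cannot interpret {value!r} as a date")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated monitoring cohort.

    Defaults emulate the retrospective study conditions: two 292-day
    periods, a right-skewed daily behavior process whose typical 7-day
    rolling level sits in the 'occasional' band, ~3 pruritic flares per
    dog per period, ~2 clinic visits per dog per period, and an
    owner-response probability that is zero in period 1 (alerts not yet
    shown to owners) and positive in period 2.
    """

    n_dogs: int = 1000
    period_start: dt.date = dt.date(2019, 1, 2)
    period_length_days: int = 292
    n_periods: int = 2
    baseline_scratch_mean: float = 80.0  # seconds/day
    baseline_lick_mean: float = 12.0  # minutes/day
    scratch_shape: float = 4.0  # gamma shape of daily scratch seconds
    lick_shape: float = 4.0  # gamma shape of daily lick minutes
    flare_rate: float = 3.0  # expected flares per dog per period
    flare_magnitude: float = 3.0  # multiplicative uplift on flare days
    flare_duration_days: int = 7
    wear_prob: float = 0.9  # probability a day is full wear
    partial_wear_fraction_range: tuple[float, float] = (0.3, 1.0)
    baseline_visit_rate: float = 2.0  # visits per dog per period
    response_prob_pre: float = 0.0  # induced-visit probability per alert, period 1
    response_prob_post: float = 0.03  # same, period 2
    dermatitis_outcome_prob: float = 0.5  # induced visits
    baseline_dermatitis_prob: float = 0.3  # baseline-propensity visits
    prescriptions_per_visit: float = 0.7  # Poisson mean per visit
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "period_start", _as_date(self.period_start))
        rng_lo, rng_hi = self.partial_wear_fraction_range
        object.__setattr__(
            self, "partial_wear_fraction_range", (float(rng_lo), float(rng_hi))
        )
        self._validate()

    def _validate(self) -> None:
        def positive_int(name):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v <= 0:
                raise ConfigurationError(f"{name}: must be a positive integer, got {v!r}")

        def nonneg(name):
            v = getattr(self, name)
            if not v >= 0:
                raise ConfigurationError(f"{name}: must be nonnegative, got {v!r}")

        def prob(name):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: must lie in [0, 1], got {v!r}")

        for name in ("n_dogs", "period_length_days", "n_periods", "flare_duration_days"):
            positive_int(name)
        for name in (
            "baseline_scratch_mean",
            "baseline_lick_mean",
            "flare_rate",
            "flare_magnitude",
            "baseline_visit_rate",
            "prescriptions_per_visit",
        ):
            nonneg(name)
        for name in ("scratch_shape", "lick_shape"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name}: must be positive")
        for name in (
            "wear_prob",
            "response_prob_pre",
            "response_prob_post",
            "dermatitis_outcome_prob",
            "baseline_dermatitis_prob",
        ):
            prob(name)
        lo, hi = self.partial_wear_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                "partial_wear_fraction_range: must be an interval within [0, 1], "
                f"got {self.partial_wear_fraction_range!r}"
            )
        if not isinstance(self.rng_seed, int) or isinstance(self.rng_seed, bool):
            raise ConfigurationError(f"rng_seed: must be an integer, got {self.rng_seed!r}")

    # -- study-span helpers -------------------------------------------------

    @property
    def n_days(self) -> int:
        """Total study span in days (period_length_days x n_periods)."""
        return self.period_length_days * self.n_periods

    @property
    def study_end(self) -> dt.date:
        """Last calendar day of the study span (inclusive)."""
        return self.period_start + dt.timedelta(days=self.n_days - 1)

    def period_bounds(self, period: int) -> tuple[dt.date, dt.date]:
        """Inclusive (start, end) dates of 1-based ``period``."""
        if not 1 <= period <= self.n_periods:
            raise ConfigurationError(f"period: must be in 1..{self.n_periods}")
        start = self.period_start + dt.timedelta(days=(period - 1) * self.period_length_days)
        end = start + dt.timedelta(days=self.period_length_days - 1)
        return start, end

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_start"] = self.period_start.isoformat()
        d["partial_wear_fraction_range"] = list(self.partial_wear_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration field(s): {sorted(unknown)}")
        d = dict(d)
        if "partial_wear_fraction_range" in d:
            d["partial_wear_fraction_range"] = tuple(d["partial_wear_fraction_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path}: expected a mapping of fields")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable sha256 of the canonical JSON form (used in run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def period_of_dates(dates, period_start: dt.date, period_length_days: int, n_periods: int):
    """1-based period index of each date; 0 before the study, n_periods+1 after.

    ``dates`` may be a pandas Series/DatetimeIndex or array of dates.
    """
    import numpy as np
    import pandas as pd

    d = pd.to_datetime(pd.Series(dates).to_numpy())
    offset = (d - pd.Timestamp(period_start)).days
    period = offset // period_length_days + 1
    period = np.clip(period, 0, n_periods + 1)
    period = np.where(offset < 0, 0, period)
    return period.astype(int)
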