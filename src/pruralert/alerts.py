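"""Pruritus alert generation and per-dog alert burden summaries.

An alert is raised on a dog-day when the 7-day rolling scratching or
licking level has risen by one or more severity levels relative to the
comparison day (the most recent prior day with sufficient data, at most
7 days back).  Additional gating mirrors the deployed system: a 7-day
baseline of usage must precede any alert, so the earliest possible alert
falls on day 9 of collar usage, and both the alert day and the
comparison day must satisfy the 3.5-of-7-days wear-sufficiency rule.
Scratch and lick rises on the same day collapse to a single alert with
trigger ``both``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import period_of_dates
from .exceptions import InputError

__all__ = ["generate_alerts", "summarize_alerts", "AlertSummary"]

EARLIEST_ALERT_DAY_OF_USE = 9  # first 8 calendar days from first wear are ineligible
COMPARISON_LOOKBACK_DAYS = 7

ALERT_COLUMNS = [
    "alert_id",
    "dog_id",
    "date",
    "trigger",
    "scratch_level_at_alert",
    "lick_level_at_alert",
    "period",
]


def generate_alerts(
    timeline: pd.DataFrame,
    *,
    period_start=None,
    period_length_days: int | None = None,
    n_periods: int = 2,
    lookback_days: int = COMPARISON_LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Emit one alert per dog-day on which a severity level rose.

    Parameters
    ----------
    timeline
        Output of :func:`pruralert.behavior.compute_timeline`.
    period_start, period_length_days, n_periods
        Study design used to tag each alert with its 1-based period.
        When omitted, the timeline's date range is split into
        ``n_periods`` equal intervals.
    lookback_days
        Maximum age of the comparison day.  A day with no sufficient
        prior day within this span raises no alert.

    Returns
    -------
    DataFrame with columns ``alert_id, dog_id, date, trigger,
    scratch_level_at_alert, lick_level_at_alert, period`` sorted by
    (dog_id, date).
    """
    required = {"dog_id", "date", "sufficient", "scratch_level", "lick_level",
                "days_since_first_wear"}
    missing = required - set(timeline.columns)
    if missing:
        raise InputError(f"timeline: missing column(s) {sorted(missing)}")

    tl = timeline.sort_values(["dog_id", "date"], kind="stable")
    dogs = pd.Index(tl["dog_id"].unique())
    grid = pd.DatetimeIndex(np.sort(pd.to_datetime(tl["date"]).unique()))
    n_dogs, n_days = len(dogs), len(grid)
    if len(tl) != n_dogs * n_days:
        raise InputError("timeline: expected one row per dog per study day")

    def pivot(col, fill, dtype):
        m = tl.pivot(index="dog_id", columns="date", values=col)
        m = m.reindex(index=dogs, columns=grid)
        return np.nan_to_num(m.to_numpy(dtype=float), nan=fill).astype(dtype)

    suff = pivot("sufficient", 0.0, bool)
    lvl_s = pivot("scratch_level", -1.0, int)
    lvl_l = pivot("lick_level", -1.0, int)
    dsfw = pivot("days_since_first_wear", -1.0, int)

    # Most recent strictly-prior sufficient day, per dog.
    comp_idx = np.full((n_dogs, n_days), -1, dtype=int)
    last = np.full(n_dogs, -1, dtype=int)
    for j in range(n_days):
        comp_idx[:, j] = last
        last = np.where(suff[:, j], j, last)

    day_idx = np.arange(n_days)[None, :]
    has_comp = (comp_idx >= 0) & (day_idx - comp_idx <= lookback_days)
    safe_comp = np.maximum(comp_idx, 0)
    comp_s = np.take_along_axis(lvl_s, safe_comp, axis=1)
    comp_l = np.take_along_axis(lvl_l, safe_comp, axis=1)

    eligible = (
        suff
        & has_comp
        & (dsfw >= EARLIEST_ALERT_DAY_OF_USE - 1)
        & (lvl_s >= 0)
        & (lvl_l >= 0)
        & (comp_s >= 0)
        & (comp_l >= 0)
    )
    rise_s = eligible & (lvl_s > comp_s)
    rise_l = eligible & (lvl_l > comp_l)
    fire = rise_s | rise_l

    di, dj = np.nonzero(fire)
    trigger = np.where(
        rise_s[di, dj] & rise_l[di, dj], "both", np.where(rise_s[di, dj], "scratch", "lick")
    )
    dates = grid.to_numpy()[dj]
    if period_start is None or period_length_days is None:
        period_start = grid[0].date()
        period_length_days = int(np.ceil(n_days / n_periods))
    elif isinstance(period_start, str):
        period_start = dt.date.fromisoformat(period_start)

    alerts = pd.DataFrame(
        {
            "dog_id": dogs.to_numpy()[di],
            "date": dates,
            "trigger": trigger,
            "scratch_level_at_alert": lvl_s[di, dj],
            "lick_level_at_alert": lvl_l[di, dj],
        }
    )
    alerts = alerts.sort_values(["dog_id", "date"], kind="stable").reset_index(drop=True)
    alerts.insert(0, "alert_id", np.arange(len(alerts)))
    if len(alerts):
        alerts["period"] = period_of_dates(
            alerts["date"], period_start, period_length_days, n_periods
        )
    else:
        alerts["period"] = pd.Series([], dtype=int)
    return alerts[ALERT_COLUMNS]


@dataclass(frozen=True)
class AlertSummary:
    """Alert burden over one period's eligible dogs."""

    period: int
    n_dogs: int
    total_alerts: int
    mean_per_dog: float
    median_per_dog: float
    range: int
    max_per_dog: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_alerts(alerts: pd.DataFrame, dogs_in_period, period: int) -> AlertSummary:
    """Distribution of per-dog alert counts over an eligible dog set.

    Dogs in ``dogs_in_period`` with zero alerts contribute zeros to the
    distribution, mirroring how per-dog averages are reported.
    """
    dogs = pd.Index(dogs_in_period).unique()
    if len(dogs) == 0:
        raise InputError("dogs_in_period: empty eligible dog set")
    sub = alerts[(alerts["period"] == period) & alerts["dog_id"].isin(dogs)]
    counts = sub.groupby("dog_id").size().reindex(dogs, fill_value=0)
    return AlertSummary(
        period=period,
        n_dogs=len(dogs),
        total_alerts=int(counts.sum()),
        mean_per_dog=float(counts.mean()),
        median_per_dog=float(counts.median()),
        range=int(counts.max() - counts.min()),
        max_per_dog=int(counts.max()),
    )
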