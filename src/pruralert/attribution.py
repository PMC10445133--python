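"""Attribution of clinic visits and prescriptions to pruritus alerts.

The primary endpoint pairs each alert with the *first* clinic visit of
the same dog occurring within a 4-week (28-day) window after the alert.
Matching is greedy, chronological, and one-to-one: alerts are processed
in date order and each consumes the earliest not-yet-matched visit in
its window, so a visit discharges at most one alert and an alert claims
at most one visit.  Visits before any alert, beyond every window, or
already consumed remain ordinary (non-alert) visits.

Dogs are also stratified into dermatitis subgroups by their number of
first-period visits carrying a dermatitis outcome (0 / 1 / 2–5 / ≥6 →
groups 0–3), and each prescription is flagged when its visit falls
within the 4-week window after any alert of the same dog.
"""

from __future__ import annotations

from bisect import bisect_left

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "match_alert_visits",
    "assign_subgroups",
    "attribute_prescriptions",
    "bin_matches_by_week",
    "week_bin_of_lag",
]

DEFAULT_WINDOW_DAYS = 28

MATCH_COLUMNS = [
    "alert_id",
    "visit_id",
    "dog_id",
    "alert_date",
    "visit_date",
    "lag_days",
    "week_bin",
]


def week_bin_of_lag(lag_days):
    """Week bin 1-4 of a 0-28 day lag; lags 0-7 → 1, 8-14 → 2, ..."""
    lag = np.asarray(lag_days, dtype=int)
    return (np.maximum(lag, 1) + 6) // 7


def match_alert_visits(
    alerts: pd.DataFrame, visits: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.DataFrame:
    """Greedy one-to-one pairing of alerts with first qualifying visits.

    Returns one row per matched pair with the lag in days (0 ≤ lag ≤
    ``window_days``) and its week bin.  Unmatched alerts and visits are
    simply absent from the result; conservation of totals is therefore
    ``len(matches) + unmatched = len(alerts)`` on the alert side and
    likewise for visits.
    """
    if window_days < 0:
        raise ConfigurationError(f"window_days: must be nonnegative, got {window_days}")
    for df, cols, name in (
        (alerts, {"alert_id", "dog_id", "date"}, "alerts"),
        (visits, {"visit_id", "dog_id", "date"}, "visits"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise InputError(f"{name}: missing column(s) {sorted(missing)}")

    a = alerts[["alert_id", "dog_id", "date"]].copy()
    v = visits[["visit_id", "dog_id", "date"]].copy()
    a["date"] = pd.to_datetime(a["date"])
    v["date"] = pd.to_datetime(v["date"])
    a = a.sort_values(["dog_id", "date", "alert_id"], kind="stable")
    v = v.sort_values(["dog_id", "date", "visit_id"], kind="stable")

    rows = []
    visit_groups = {dog: grp for dog, grp in v.groupby("dog_id", sort=False)}
    for dog, agrp in a.groupby("dog_id", sort=False):
        vgrp = visit_groups.get(dog)
        if vgrp is None:
            continue
        vdays = list(vgrp["date"].astype("int64") // 86_400_000_000_000)
        vids = list(vgrp["visit_id"])
        vdates = list(vgrp["date"])
        for aid, adate in zip(agrp["alert_id"], agrp["date"]):
            if not vdays:
                break
            aday = adate.value // 86_400_000_000_000
            i = bisect_left(vdays, aday)
            if i < len(vdays) and vdays[i] - aday <= window_days:
                lag = int(vdays[i] - aday)
                rows.append((aid, vids[i], dog, adate, vdates[i], lag))
                del vdays[i], vids[i], vdates[i]

    matches = pd.DataFrame(
        rows, columns=["alert_id", "visit_id", "dog_id", "alert_date", "visit_date", "lag_days"]
    )
    if len(matches):
        matches["week_bin"] = week_bin_of_lag(matches["lag_days"])
    else:
        matches["week_bin"] = pd.Series([], dtype=int)
    return matches[MATCH_COLUMNS].reset_index(drop=True)


def assign_subgroups(
    visits: pd.DataFrame, period1_bounds, dogs=None
) -> pd.DataFrame:
    """Dermatitis subgroup (0-3) per dog from first-period outcome visits.

    Parameters
    ----------
    visits
        Table with ``dog_id``, ``date``, ``dermatitis_outcome``.
    period1_bounds
        Inclusive (start, end) dates of the first period.
    dogs
        Optional full roster; dogs without any first-period visit are
        assigned group 0.
    """
    start, end = (pd.Timestamp(period1_bounds[0]), pd.Timestamp(period1_bounds[1]))
    v = visits.copy()
    v["date"] = pd.to_datetime(v["date"])
    in_p1 = (v["date"] >= start) & (v["date"] <= end)
    derm = v[in_p1 & v["dermatitis_outcome"].astype(bool)]
    counts = derm.groupby("dog_id").size()
    roster = pd.Index(dogs).unique() if dogs is not None else pd.Index(v["dog_id"].unique())
    counts = counts.reindex(roster, fill_value=0)
    group = np.select(
        [counts == 0, counts == 1, counts <= 5], [0, 1, 2], default=3
    )
    return pd.DataFrame({"dog_id": roster, "group": group.astype(int)})


def attribute_prescriptions(
    prescriptions: pd.DataFrame,
    visits: pd.DataFrame,
    alerts: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Flag each prescription whose visit falls 0-``window_days`` days after any alert.

    The flag depends only on the visit date, so all prescriptions at one
    qualifying visit are flagged together.  A prescription whose
    ``visit_id`` is absent from ``visits`` raises :class:`InputError`.
    """
    if window_days < 0:
        raise ConfigurationError(f"window_days: must be nonnegative, got {window_days}")
    rx = prescriptions.copy()
    vis = visits[["visit_id", "dog_id", "date"]].copy()
    vis["date"] = pd.to_datetime(vis["date"])
    merged = rx.merge(vis, on="visit_id", how="left", suffixes=("", "_visit"))
    if merged["date"].isna().any():
        orphans = merged.loc[merged["date"].isna(), "prescription_id"].tolist()[:5]
        raise InputError(f"prescriptions: no matching visit for prescription(s) {orphans}")

    al = alerts[["dog_id", "date"]].copy()
    al["date"] = pd.to_datetime(al["date"])
    alert_days = {
        dog: np.sort(grp["date"].astype("int64").to_numpy()) // 86_400_000_000_000
        for dog, grp in al.groupby("dog_id", sort=False)
    }

    vdays = merged["date"].astype("int64").to_numpy() // 86_400_000_000_000
    flags = np.zeros(len(merged), dtype=bool)
    for i, (dog, day) in enumerate(zip(merged["dog_id"], vdays)):
        days = alert_days.get(dog)
        if days is None:
            continue
        j = np.searchsorted(days, day, side="right")
        flags[i] = j > 0 and day - days[j - 1] <= window_days
    rx = prescriptions.copy()
    rx["within_4wk_of_alert"] = flags
    return rx


def bin_matches_by_week(matches: pd.DataFrame, total_visits: int | None = None) -> pd.Series:
    """Counts of matched visits per week bin 1-4, plus visits outside the window.

    When ``total_visits`` is given, an ``outside`` entry counts the
    remaining (non-alert) visits.
    """
    counts = (
        matches.groupby("week_bin").size().reindex([1, 2, 3, 4], fill_value=0)
        if len(matches)
        else pd.Series(0, index=[1, 2, 3, 4])
    )
    counts.index.name = "week_bin"
    if total_visits is not None:
        outside = int(total_visits) - int(counts.sum())
        counts = pd.concat([counts, pd.Series({"outside": outside})])
    return counts.astype(int)
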