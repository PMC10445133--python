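"""Rolling behavior averages, severity levels, and data sufficiency.

The monitoring system summarises each dog-day as total scratching
(seconds/day) and total licking (minutes/day), displays a trailing 7-day
rolling average of each, and bins the rolling averages into four ordered
severity levels:

========== ===================== ===================
level      scratching (s/day)    licking (min/day)
========== ===================== ===================
infrequent [0, 53)               [0, 7)
occasional [53, 120)             [7, 19)
elevated   [120, 300)            [19, 43)
severe     [300, inf)            [43, inf)
========== ===================== ===================

Bins are lower-inclusive / upper-exclusive, so a rolling mean exactly at
a cut point falls in the higher level.  Days without collar wear
contribute nothing to the rolling mean; a day's statistics are
"sufficient" only when the wear fractions of its trailing 7-day window
sum to at least 3.5 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "LEVEL_NAMES",
    "LevelThresholds",
    "categorize",
    "wear_sufficiency",
    "rolling_mean_7d",
    "compute_timeline",
]

LEVEL_NAMES = ("infrequent", "occasional", "elevated", "severe")

ROLLING_WINDOW_DAYS = 7
MIN_WEAR_DAYS = 3.5


@dataclass(frozen=True)
class LevelThresholds:
    """Cut points separating the four severity levels (lower-inclusive)."""

    scratch_bounds: tuple[float, float, float] = (53.0, 120.0, 300.0)
    lick_bounds: tuple[float, float, float] = (7.0, 19.0, 43.0)

    def __post_init__(self):
        for name in ("scratch_bounds", "lick_bounds"):
            b = tuple(float(x) for x in getattr(self, name))
            if len(b) != 3:
                raise InputError(f"{name}: expected exactly 3 cut points, got {len(b)}")
            if not (0 < b[0] < b[1] < b[2]):
                raise InputError(f"{name}: cut points must be strictly ascending and positive")
            object.__setattr__(self, name, b)

    def bounds_for(self, metric: str) -> tuple[float, float, float]:
        if metric == "scratch":
            return self.scratch_bounds
        if metric == "lick":
            return self.lick_bounds
        raise InputError(f"metric: expected 'scratch' or 'lick', got {metric!r}")


def categorize(value, metric: str, thresholds: LevelThresholds | None = None):
    """Severity level (0-3) of a rolling-mean value.

    Accepts a scalar or array.  NaN values map to NaN (no level).
    Negative values raise :class:`InputError`.
    """
    thresholds = thresholds or LevelThresholds()
    bounds = np.asarray(thresholds.bounds_for(metric), dtype=float)
    arr = np.asarray(value, dtype=float)
    finite = ~np.isnan(arr)
    if np.any(arr[finite] < 0):
        raise InputError(f"{metric} value: rolling means must be nonnegative")
    levels = np.searchsorted(bounds, arr, side="right").astype(float)
    levels = np.where(finite, levels, np.nan)
    if np.isscalar(value) or np.ndim(value) == 0:
        lv = float(levels)
        return int(lv) if not np.isnan(lv) else np.nan
    return levels


def wear_sufficiency(window, minimum: float = MIN_WEAR_DAYS) -> bool:
    """True when a 7-entry window of wear fractions sums to >= ``minimum`` days."""
    w = np.asarray(window, dtype=float)
    if w.shape != (ROLLING_WINDOW_DAYS,):
        raise InputError(
            f"window: expected exactly {ROLLING_WINDOW_DAYS} wear fractions, got shape {w.shape}"
        )
    if np.any((w < 0) | (w > 1)):
        raise InputError("window: wear fractions must lie in [0, 1]")
    return bool(w.sum() >= minimum)


def _trailing_sum(arr: np.ndarray, window: int) -> np.ndarray:
    """Trailing windowed sum along the last axis; partial windows at the start."""
    cs = np.cumsum(arr, axis=-1, dtype=float)
    out = cs.copy()
    out[..., window:] = cs[..., window:] - cs[..., :-window]
    return out


def rolling_mean_7d(values, wear_fractions, window: int = ROLLING_WINDOW_DAYS):
    """Trailing ``window``-day mean over wear days of one date-contiguous series.

    The mean on day *d* is taken over days in {d-6, ..., d} with
    wear_fraction > 0; no-wear days are excluded rather than treated as
    zeros.  Days whose whole window has zero wear yield NaN.
    """
    vals = np.asarray(values, dtype=float)
    wear = np.asarray(wear_fractions, dtype=float)
    if vals.shape != wear.shape or vals.ndim != 1:
        raise InputError("values and wear_fractions must be 1-D arrays of equal length")
    return _rolling_mean_2d(vals[None, :], wear[None, :], window)[0]


def _rolling_mean_2d(vals: np.ndarray, wear: np.ndarray, window: int) -> np.ndarray:
    observed = wear > 0
    sums = _trailing_sum(np.where(observed, vals, 0.0), window)
    counts = _trailing_sum(observed.astype(float), window)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return means


def _check_contiguous(behavior: pd.DataFrame) -> None:
    dup = behavior.duplicated(subset=["dog_id", "date"])
    if dup.any():
        raise InputError("behavior table: duplicate (dog_id, date) records")
    for dog, grp in behavior.groupby("dog_id", sort=False):
        d = pd.to_datetime(grp["date"])
        span = (d.max() - d.min()).days + 1
        if span != len(d):
            raise InputError(f"behavior table: dates for dog {dog!r} are not contiguous")


def compute_timeline(
    behavior: pd.DataFrame,
    thresholds: LevelThresholds | None = None,
    min_wear_days: float = MIN_WEAR_DAYS,
    window: int = ROLLING_WINDOW_DAYS,
) -> pd.DataFrame:
    """Per dog-day rolling means, severity levels, and sufficiency flags.

    Parameters
    ----------
    behavior
        Long table with columns ``dog_id``, ``date``, ``scratch_seconds``,
        ``lick_minutes``, ``wear_fraction``; dates contiguous per dog.
    thresholds
        Level cut points; defaults to the deployed system's values.
    min_wear_days
        Minimum summed wear (days) in the trailing window for a day's
        levels to be considered established.

    Returns
    -------
    DataFrame with one row per dog-day: rolling_scratch, rolling_lick,
    wear_sum_7d, sufficient, days_since_first_wear (−1 before any wear),
    scratch_level, lick_level (NaN when not sufficient).
    """
    required = {"dog_id", "date", "scratch_seconds", "lick_minutes", "wear_fraction"}
    missing = required - set(behavior.columns)
    if missing:
        raise InputError(f"behavior table: missing column(s) {sorted(missing)}")
    thresholds = thresholds or LevelThresholds()
    behavior = behavior.copy()
    behavior["date"] = pd.to_datetime(behavior["date"])
    _check_contiguous(behavior)

    # Common daily grid; a dog absent on a grid day is treated as no-wear.
    grid = pd.date_range(behavior["date"].min(), behavior["date"].max(), freq="D")
    dogs = pd.Index(behavior["dog_id"].unique())

    def pivot(col):
        return (
            behavior.pivot(index="dog_id", columns="date", values=col)
            .reindex(index=dogs, columns=grid)
            .to_numpy(dtype=float)
        )

    scratch = pivot("scratch_seconds")
    lick = pivot("lick_minutes")
    wear = pivot("wear_fraction")
    wear = np.nan_to_num(wear, nan=0.0)
    scratch = np.nan_to_num(scratch, nan=0.0)
    lick = np.nan_to_num(lick, nan=0.0)
    if np.any((wear < 0) | (wear > 1)):
        raise InputError("behavior table: wear_fraction must lie in [0, 1]")
    if np.any(scratch < 0) or np.any(lick < 0):
        raise InputError("behavior table: behavior totals must be nonnegative")

    roll_s = _rolling_mean_2d(scratch, wear, window)
    roll_l = _rolling_mean_2d(lick, wear, window)
    wear_sum = _trailing_sum(wear, window)
    sufficient = wear_sum >= min_wear_days

    worn = wear > 0
    any_wear = worn.any(axis=1)
    first = np.where(any_wear, worn.argmax(axis=1), np.iinfo(np.int64).max)
    dsfw = np.arange(len(grid))[None, :] - first[:, None]  # negative before first wear
    dsfw = np.where(any_wear[:, None], dsfw, -1)
    dsfw = np.maximum(dsfw, -1)

    lvl_s = categorize(np.where(sufficient, roll_s, np.nan), "scratch", thresholds)
    lvl_l = categorize(np.where(sufficient, roll_l, np.nan), "lick", thresholds)

    n_dogs, n_days = roll_s.shape
    out = pd.DataFrame(
        {
            "dog_id": np.repeat(dogs.to_numpy(), n_days),
            "date": np.tile(grid.to_numpy(), n_dogs),
            "rolling_scratch": roll_s.ravel(),
            "rolling_lick": roll_l.ravel(),
            "wear_sum_7d": wear_sum.ravel(),
            "sufficient": sufficient.ravel(),
            "days_since_first_wear": dsfw.ravel().astype(int),
            "scratch_level": lvl_s.ravel(),
            "lick_level": lvl_l.ravel(),
        }
    )
    return out
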