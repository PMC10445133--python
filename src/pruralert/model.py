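"""Model/results interface for the alert-response analysis.

:class:`AlertResponseModel` bundles the full observational analysis:
from per-dog daily telemetry and clinic-visit tables it computes rolling
severity levels, generates pruritus alerts, matches alerts to first
clinic visits within the 4-week window, stratifies dogs into dermatitis
subgroups, and estimates pre/post odds ratios of an alert being followed
by a visit.  ``fit()`` returns an :class:`AlertResponseResults` carrying
the estimates, their confidence intervals, per-period descriptive
summaries, and a ``summary()`` table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alerts import generate_alerts, summarize_alerts
from .attribution import (
    DEFAULT_WINDOW_DAYS,
    assign_subgroups,
    attribute_prescriptions,
    bin_matches_by_week,
    match_alert_visits,
)
from .behavior import LevelThresholds, compute_timeline
from .config import CohortConfig, period_of_dates
from .exceptions import ConfigurationError
from .stats import build_two_by_two, fraction, odds_ratio, results_frame

__all__ = ["AlertResponseModel", "AlertResponseResults"]

ELIGIBILITY_MODES = ("visit_and_alert", "alert_only")


class AlertResponseModel:
    """Pre/post alert-visit odds-ratio model for a monitored dog cohort.

    Parameters
    ----------
    behavior
        Per dog-day telemetry: ``dog_id, date, scratch_seconds,
        lick_minutes, wear_fraction``.
    visits
        Clinic visits: ``visit_id, dog_id, date, dermatitis_outcome``.
    prescriptions
        Optional prescriptions: ``prescription_id, visit_id, drug_name``.
    period_start, period_length_days, n_periods
        Study design; inferred from the behavior date range (split into
        ``n_periods`` equal intervals) when omitted.
    window_days
        Attribution window after an alert (default 28).
    eligibility
        ``visit_and_alert`` (default) includes a dog in a period only if
        it has at least one alert *and* one clinic visit in that period,
        as in the source study; ``alert_only`` drops the visit condition
        (useful in simulation experiments, where conditioning on the
        outcome would bias the estimand).
    """

    def __init__(
        self,
        behavior: pd.DataFrame,
        visits: pd.DataFrame,
        prescriptions: Optional[pd.DataFrame] = None,
        *,
        thresholds: Optional[LevelThresholds] = None,
        window_days: int = DEFAULT_WINDOW_DAYS,
        period_start=None,
        period_length_days: Optional[int] = None,
        n_periods: int = 2,
        min_wear_days: float = 3.5,
        eligibility: str = "visit_and_alert",
    ):
        if eligibility not in ELIGIBILITY_MODES:
            raise ConfigurationError(
                f"eligibility: expected one of {ELIGIBILITY_MODES}, got {eligibility!r}"
            )
        if window_days < 0:
            raise ConfigurationError(f"window_days: must be nonnegative, got {window_days}")
        self.behavior = behavior
        self.visits = visits
        self.prescriptions = prescriptions
        self.thresholds = thresholds or LevelThresholds()
        self.window_days = int(window_days)
        self.n_periods = int(n_periods)
        self.min_wear_days = float(min_wear_days)
        self.eligibility = eligibility

        dates = pd.to_datetime(behavior["date"])
        if period_start is None:
            period_start = dates.min().date()
        elif isinstance(period_start, str):
            period_start = dt.date.fromisoformat(period_start)
        if period_length_days is None:
            span = (dates.max() - pd.Timestamp(period_start)).days + 1
            period_length_days = int(np.ceil(span / n_periods))
        self.period_start = period_start
        self.period_length_days = int(period_length_days)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_simulation(cls, config: CohortConfig, **kwargs) -> "AlertResponseModel":
        """Simulate a cohort under ``config`` and build the model on it."""
        from .simulate import simulate_cohort

        behavior, visits, prescriptions = simulate_cohort(config)
        kwargs.setdefault("period_start", config.period_start)
        kwargs.setdefault("period_length_days", config.period_length_days)
        kwargs.setdefault("n_periods", config.n_periods)
        return cls(behavior, visits, prescriptions, **kwargs)

    @classmethod
    def from_csv(
        cls, behavior_path, visits_path, prescriptions_path=None, **kwargs
    ) -> "AlertResponseModel":
        behavior = pd.read_csv(behavior_path, parse_dates=["date"])
        visits = pd.read_csv(visits_path, parse_dates=["date"])
        rx = pd.read_csv(prescriptions_path) if prescriptions_path else None
        return cls(behavior, visits, rx, **kwargs)

    # -- helpers ------------------------------------------------------------

    def period_bounds(self, period: int) -> tuple[dt.date, dt.date]:
        start = self.period_start + dt.timedelta(days=(period - 1) * self.period_length_days)
        return start, start + dt.timedelta(days=self.period_length_days - 1)

    def _periods_of(self, dates) -> np.ndarray:
        return period_of_dates(
            dates, self.period_start, self.period_length_days, self.n_periods
        )

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "AlertResponseResults":
        timeline = compute_timeline(
            self.behavior, thresholds=self.thresholds, min_wear_days=self.min_wear_days
        )
        alerts = generate_alerts(
            timeline,
            period_start=self.period_start,
            period_length_days=self.period_length_days,
            n_periods=self.n_periods,
        )

        visits = self.visits.copy()
        visits["date"] = pd.to_datetime(visits["date"])
        visits["period"] = self._periods_of(visits["date"])

        # Per-period eligible dog sets.
        eligible: dict[int, pd.Index] = {}
        for p in range(1, self.n_periods + 1):
            dogs_alert = pd.Index(alerts.loc[alerts["period"] == p, "dog_id"].unique())
            if self.eligibility == "visit_and_alert":
                dogs_visit = pd.Index(visits.loc[visits["period"] == p, "dog_id"].unique())
                eligible[p] = dogs_alert.intersection(dogs_visit).sort_values()
            else:
                eligible[p] = dogs_alert.sort_values()

        keep = np.zeros(len(alerts), dtype=bool)
        for p, dogs in eligible.items():
            keep |= (alerts["period"] == p).to_numpy() & alerts["dog_id"].isin(dogs).to_numpy()
        alerts_elig = alerts[keep].reset_index(drop=True)

        all_eligible_dogs = pd.Index(np.sort(np.unique(np.concatenate(
            [d.to_numpy() for d in eligible.values()] or [np.array([], dtype=object)]
        ))))
        visits_elig = visits[visits["dog_id"].isin(all_eligible_dogs)].reset_index(drop=True)

        matches = match_alert_visits(alerts_elig, visits_elig, self.window_days)

        subgroups = assign_subgroups(
            visits_elig, self.period_bounds(1), dogs=all_eligible_dogs
        )

        tables = {
            "combined": build_two_by_two(alerts_elig, matches, None),
            "scratch": build_two_by_two(alerts_elig, matches, "scratch_level"),
            "lick": build_two_by_two(alerts_elig, matches, "lick_level"),
        }
        or_results = {
            key: [odds_ratio(t) for t in tbls if min(t.a + t.b, t.c + t.d) > 0
                  and t.a + t.c > 0 and t.b + t.d > 0]
            for key, tbls in tables.items()
        }

        alert_summaries = {
            p: summarize_alerts(alerts_elig, eligible[p], p)
            for p in range(1, self.n_periods + 1)
            if len(eligible[p])
        }

        # Visit-side accounting: matched flag, week-bin tables by period/subgroup.
        visits_elig = visits_elig.merge(
            matches[["visit_id", "week_bin"]], on="visit_id", how="left"
        )
        visits_elig["is_alert_visit"] = visits_elig["week_bin"].notna()
        visits_elig = visits_elig.merge(subgroups, on="dog_id", how="left")

        week_tables = {}
        for p in range(1, self.n_periods + 1):
            vp = visits_elig[
                (visits_elig["period"] == p) & visits_elig["dog_id"].isin(eligible[p])
            ]
            rows = {}
            for g, grp in vp.groupby("group"):
                m = grp[grp["is_alert_visit"]]
                rows[int(g)] = bin_matches_by_week(m, total_visits=len(grp))
            rows["total"] = bin_matches_by_week(
                vp[vp["is_alert_visit"]], total_visits=len(vp)
            )
            week_tables[p] = pd.DataFrame(rows).T

        rx_summary = None
        rx_flagged = None
        # prescriptions at visits of ineligible dogs fall outside the analysis
        rx_in = (
            self.prescriptions[
                self.prescriptions["visit_id"].isin(set(visits_elig["visit_id"]))
            ]
            if self.prescriptions is not None
            else None
        )
        if rx_in is not None and len(rx_in):
            rx_flagged = attribute_prescriptions(
                rx_in, visits_elig, alerts_elig, self.window_days
            )
            rx = rx_flagged.merge(
                visits_elig[["visit_id", "period", "dog_id"]], on="visit_id", how="inner"
            )
            rows = []
            for p in range(1, self.n_periods + 1):
                rp = rx[(rx["period"] == p) & rx["dog_id"].isin(eligible[p])]
                total = len(rp)
                flagged = int(rp["within_4wk_of_alert"].sum())
                rows.append(
                    {
                        "period": p,
                        "total_medications": total,
                        "within_window": flagged,
                        "within_window_pct": fraction(flagged, total) if total else np.nan,
                    }
                )
            rx_summary = pd.DataFrame(rows)

        return AlertResponseResults(
            model=self,
            timeline=timeline,
            alerts=alerts_elig,
            all_alerts=alerts,
            matches=matches,
            visits=visits_elig,
            subgroups=subgroups,
            eligible=eligible,
            tables=tables,
            or_results=or_results,
            alert_summaries=alert_summaries,
            week_tables=week_tables,
            prescriptions=rx_flagged,
            prescription_summary=rx_summary,
        )


@dataclass
class AlertResponseResults:
    """Fitted alert-response analysis.

    Attributes of interest: ``odds_ratio``, ``conf_int``, ``pvalue``
    (combined table); ``or_results`` per stratum; ``alert_summaries``
    per period; ``week_tables`` (visit-side week-bin tables by
    dermatitis subgroup); ``prescription_summary``.
    """

    model: AlertResponseModel
    timeline: pd.DataFrame
    alerts: pd.DataFrame
    all_alerts: pd.DataFrame
    matches: pd.DataFrame
    visits: pd.DataFrame
    subgroups: pd.DataFrame
    eligible: dict
    tables: dict
    or_results: dict
    alert_summaries: dict
    week_tables: dict
    prescriptions: Optional[pd.DataFrame] = None
    prescription_summary: Optional[pd.DataFrame] = None

    # -- headline estimates -------------------------------------------------

    @property
    def combined_result(self):
        return self.or_results["combined"][-1]

    @property
    def odds_ratio(self) -> float:
        return self.combined_result.odds_ratio

    @property
    def conf_int(self) -> tuple[float, float]:
        r = self.combined_result
        return (r.ci_low, r.ci_high)

    @property
    def pvalue(self) -> float:
        return self.combined_result.p_two_tailed

    def alert_visit_fraction(self, period: int) -> float:
        """Percentage of the period's alerts followed by a matched visit."""
        a = self.alerts[self.alerts["period"] == period]
        matched = a["alert_id"].isin(set(self.matches["alert_id"]))
        return fraction(int(matched.sum()), len(a))

    # -- presentation -------------------------------------------------------

    def strata_frame(self) -> pd.DataFrame:
        frames = []
        for metric in ("scratch", "lick", "combined"):
            f = results_frame(self.or_results[metric])
            f.insert(0, "metric", metric)
            frames.append(f)
        out = pd.concat(frames, ignore_index=True)
        return out.drop_duplicates(subset=["metric", "stratum"], keep="last")

    def summary(self) -> str:
        """Plain-text summary table in the style of a model results report."""
        lines = ["Alert-visit odds-ratio analysis (period 2 vs period 1)",
                 "=" * 56]
        for p, s in sorted(self.alert_summaries.items()):
            lines.append(
                f"period {p}: {s.n_dogs} dogs, {s.total_alerts} alerts "
                f"(mean {s.mean_per_dog:.1f}/dog, median {s.median_per_dog:.1f}, "
                f"max {s.max_per_dog})"
            )
        lines.append("-" * 56)
        lines.append(f"{'stratum':<22}{'OR':>8}{'95% CI':>16}{'p':>10}")
        for metric in ("scratch", "lick"):
            for r in self.or_results[metric]:
                if r.stratum == "combined":
                    continue
                lines.append(
                    f"{metric + '/' + r.stratum:<22}{r.odds_ratio:>8.2f}"
                    f"{f'{r.ci_low:.2f}-{r.ci_high:.2f}':>16}{r.p_display:>10}"
                )
        r = self.combined_result
        lines.append(
            f"{'combined':<22}{r.odds_ratio:>8.4f}"
            f"{f'{r.ci_low:.2f}-{r.ci_high:.2f}':>16}{r.p_display:>10}"
        )
        lines.append("-" * 56)
        for p in sorted(self.eligible):
            a = self.alerts[self.alerts["period"] == p]
            if not len(a):
                continue
            vp = self.visits[
                (self.visits["period"] == p) & self.visits["dog_id"].isin(self.eligible[p])
            ]
            lines.append(
                f"period {p}: alert visits = {self.alert_visit_fraction(p):.2f}% of alerts"
                + (f", {fraction(int(vp['is_alert_visit'].sum()), len(vp)):.1f}% of visits"
                   if len(vp) else "")
            )
        if self.prescription_summary is not None:
            for _, row in self.prescription_summary.iterrows():
                if row["total_medications"]:
                    lines.append(
                        f"period {int(row['period'])}: {row['within_window_pct']:.1f}% of "
                        f"{int(row['total_medications'])} medications within "
                        f"{self.model.window_days} days of an alert"
                    )
        return "\n".join(lines)

    def plot_alert_visit_fractions(self, ax=None):
        """Bar chart of alert visits as % of visits, by subgroup and period."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = {}
        for p, table in self.week_tables.items():
            pct = {}
            for g, row in table.iterrows():
                total = row.sum()
                matched = row[[1, 2, 3, 4]].sum()
                pct[g] = 100.0 * matched / total if total else np.nan
            data[f"period {p}"] = pct
        pd.DataFrame(data).plot.bar(ax=ax)
        ax.set_ylabel("alert visits (% of clinic visits)")
        ax.set_xlabel("dermatitis subgroup")
        return ax
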