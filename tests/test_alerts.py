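"""Alert engine: trigger rules, day-9 gating, and brute-force equivalence."""

import numpy as np
import pandas as pd
import pytest

from pruralert import (
    CohortConfig,
    InputError,
    compute_timeline,
    generate_alerts,
    simulate_cohort,
    summarize_alerts,
)
from tests.conftest import constant_behavior


def _level(value, bounds):
    return sum(value >= b for b in bounds)


def brute_force_alerts(behavior: pd.DataFrame) -> pd.DataFrame:
    """Day-by-day recomputation of the alert rules with plain Python loops.

    Independent of the vectorised timeline/alert implementation: trailing
    7-day means over worn days, 3.5-day wear sufficiency, level categories
    via explicit comparisons, day-9 usage gate, and a level-rise comparison
    against the most recent sufficient day at most 7 days back.
    """
    scratch_bounds, lick_bounds = (53, 120, 300), (7, 19, 43)
    rows = []
    for dog, grp in behavior.sort_values(["dog_id", "date"]).groupby("dog_id"):
        dates = list(pd.to_datetime(grp["date"]))
        scratch = list(grp["scratch_seconds"])
        lick = list(grp["lick_minutes"])
        wear = list(grp["wear_fraction"])
        n = len(dates)
        first_wear = next((i for i in range(n) if wear[i] > 0), None)

        suff, lvl_s, lvl_l = [], [], []
        for i in range(n):
            window = range(max(0, i - 6), i + 1)
            worn = [j for j in window if wear[j] > 0]
            suff.append(sum(wear[j] for j in window) >= 3.5)
            if worn:
                ms = sum(scratch[j] for j in worn) / len(worn)
                ml = sum(lick[j] for j in worn) / len(worn)
                lvl_s.append(_level(ms, scratch_bounds))
                lvl_l.append(_level(ml, lick_bounds))
            else:
                lvl_s.append(None)
                lvl_l.append(None)

        for i in range(n):
            if first_wear is None or i - first_wear < 8:
                continue  # earliest alert on day 9 of usage
            if not suff[i] or lvl_s[i] is None:
                continue
            comp = next(
                (j for j in range(i - 1, max(i - 8, -1), -1) if suff[j]), None
            )
            if comp is None or lvl_s[comp] is None:
                continue
            rise_s = lvl_s[i] > lvl_s[comp]
            rise_l = lvl_l[i] > lvl_l[comp]
            if rise_s or rise_l:
                trigger = "both" if (rise_s and rise_l) else ("scratch" if rise_s else "lick")
                rows.append((dog, dates[i], trigger, lvl_s[i], lvl_l[i]))
    return pd.DataFrame(
        rows,
        columns=["dog_id", "date", "trigger", "scratch_level_at_alert", "lick_level_at_alert"],
    )


def engine_alerts(behavior):
    return generate_alerts(compute_timeline(behavior))


class TestTriggerRules:
    def _step_behavior(self, step_day, lo=40.0, hi=200.0, n_days=20):
        """Scratch steps lo -> hi on ``step_day`` (1-based); lick constant."""
        b = constant_behavior("d1", "2020-01-01", n_days, scratch=lo, lick=3.0)
        b.loc[step_day - 1 :, "scratch_seconds"] = hi
        return b

    def test_level_rise_emits_single_scratch_alert(self):
        # a day-12 spike steps the rolling mean from 40 to 60 s/day,
        # crossing the 53 s/day cut exactly once
        b = constant_behavior("d1", "2020-01-01", 20, scratch=40.0, lick=3.0)
        b.loc[11, "scratch_seconds"] = 180.0  # (6*40 + 180)/7 = 60
        alerts = engine_alerts(b)
        assert len(alerts) == 1
        a = alerts.iloc[0]
        assert a["trigger"] == "scratch"
        assert a["date"] == pd.Timestamp("2020-01-12")
        assert a["scratch_level_at_alert"] == 1
        assert a["lick_level_at_alert"] == 0

    def test_consecutive_rises_each_alert(self):
        # a sustained 40 -> 200 step walks the rolling mean through two
        # cuts on different days; no cooldown suppresses the second alert
        alerts = engine_alerts(self._step_behavior(12))
        assert list(alerts["date"]) == [
            pd.Timestamp("2020-01-12"), pd.Timestamp("2020-01-15")
        ]
        assert list(alerts["scratch_level_at_alert"]) == [1, 2]

    def test_no_alert_before_day_nine(self):
        alerts = engine_alerts(self._step_behavior(8, n_days=8))
        assert len(alerts) == 0

    def test_day_nine_gate_follows_first_wear(self):
        # no wear for the first 5 days: the usage clock starts at day 6
        b = self._step_behavior(12, n_days=20)
        b.loc[:4, ["wear_fraction", "scratch_seconds", "lick_minutes"]] = 0.0
        alerts = engine_alerts(b)
        assert (pd.to_datetime(alerts["date"]) >= pd.Timestamp("2020-01-14")).all()

    def test_constant_behavior_never_alerts(self):
        b = constant_behavior("d1", "2020-01-01", 40, scratch=100.0, lick=10.0)
        assert len(engine_alerts(b)) == 0

    def test_level_decrease_never_alerts(self):
        b = constant_behavior("d1", "2020-01-01", 30, scratch=200.0, lick=30.0)
        b.loc[14:, ["scratch_seconds", "lick_minutes"]] = 0.0
        assert len(engine_alerts(b)) == 0

    def test_simultaneous_rises_collapse_to_both(self):
        b = constant_behavior("d1", "2020-01-01", 20, scratch=40.0, lick=3.0)
        b.loc[11:, "scratch_seconds"] = 400.0
        b.loc[11:, "lick_minutes"] = 50.0
        alerts = engine_alerts(b)
        # the simultaneous first crossing emits one alert with trigger=both
        assert alerts.iloc[0]["trigger"] == "both"
        assert alerts.iloc[0]["date"] == pd.Timestamp("2020-01-12")
        # at most one alert per dog-day even when both metrics rise
        assert not alerts.duplicated(subset=["dog_id", "date"]).any()

    def test_missing_sufficiency_column_rejected(self):
        with pytest.raises(InputError, match="sufficient"):
            generate_alerts(pd.DataFrame({"dog_id": [], "date": []}))


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed,wear_prob", [(1, 1.0), (2, 0.7), (3, 0.5)])
    def test_engine_equals_day_by_day_recount(self, seed, wear_prob):
        cfg = CohortConfig(
            n_dogs=40,
            period_length_days=30,
            n_periods=2,
            wear_prob=wear_prob,
            flare_rate=2.0,
            rng_seed=seed,
        )
        behavior, _, _ = simulate_cohort(cfg)
        got = engine_alerts(behavior).drop(columns=["alert_id", "period"])
        want = brute_force_alerts(behavior)
        got = got.sort_values(["dog_id", "date"]).reset_index(drop=True)
        want = want.sort_values(["dog_id", "date"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_order_invariance(self, small_cohort):
        behavior, _, _ = small_cohort
        shuffled = behavior.sample(frac=1.0, random_state=0)
        a1 = engine_alerts(behavior)
        a2 = engine_alerts(shuffled)
        cols = ["dog_id", "date", "trigger"]
        pd.testing.assert_frame_equal(
            a1[cols].sort_values(cols).reset_index(drop=True),
            a2[cols].sort_values(cols).reset_index(drop=True),
        )


class TestSummarize:
    def test_single_dog_single_alert(self):
        alerts = pd.DataFrame(
            {"alert_id": [0], "dog_id": ["d1"], "period": [1],
             "date": [pd.Timestamp("2020-01-10")]}
        )
        s = summarize_alerts(alerts, ["d1"], period=1)
        assert s.total_alerts == 1
        assert s.mean_per_dog == s.median_per_dog == s.max_per_dog == 1
        assert s.range == 0

    def test_zero_alert_dogs_count_in_denominator(self):
        alerts = pd.DataFrame(
            {"alert_id": [0, 1], "dog_id": ["d1", "d1"], "period": [1, 1],
             "date": pd.to_datetime(["2020-01-10", "2020-01-12"])}
        )
        s = summarize_alerts(alerts, ["d1", "d2"], period=1)
        assert s.mean_per_dog == pytest.approx(1.0)
        assert s.range == 2

    def test_empty_dog_set_rejected(self):
        with pytest.raises(InputError):
            summarize_alerts(pd.DataFrame({"alert_id": [], "dog_id": [], "period": []}), [], 1)

    def test_summary_equals_recount(self, medium_fit):
        for p, s in medium_fit.alert_summaries.items():
            sub = medium_fit.alerts[medium_fit.alerts["period"] == p]
            counts = sub.groupby("dog_id").size().reindex(
                medium_fit.eligible[p], fill_value=0
            )
            assert s.total_alerts == counts.sum()
            assert s.mean_per_dog == pytest.approx(counts.mean())
            assert s.max_per_dog == counts.max()
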