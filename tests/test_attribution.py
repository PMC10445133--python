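"""Alert-visit matching, dermatitis subgroups, prescription windows, week bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pruralert import (
    ConfigurationError,
    InputError,
    assign_subgroups,
    attribute_prescriptions,
    bin_matches_by_week,
    match_alert_visits,
)
from pruralert.attribution import week_bin_of_lag

START = pd.Timestamp("2020-01-01")


def alerts_at(days, dog="d1"):
    return pd.DataFrame(
        {
            "alert_id": range(len(days)),
            "dog_id": dog,
            "date": [START + pd.Timedelta(days=d) for d in days],
        }
    )


def visits_at(days, dog="d1", derm=True):
    return pd.DataFrame(
        {
            "visit_id": [100 + i for i in range(len(days))],
            "dog_id": dog,
            "date": [START + pd.Timedelta(days=d) for d in days],
            "dermatitis_outcome": derm,
        }
    )


class TestMatching:
    def test_first_visit_wins_and_second_left_unmatched(self):
        m = match_alert_visits(alerts_at([100]), visits_at([103, 110]))
        assert len(m) == 1
        assert m.iloc[0]["visit_id"] == 100
        assert m.iloc[0]["lag_days"] == 3
        assert m.iloc[0]["week_bin"] == 1

    def test_visit_beyond_window_not_matched(self):
        assert len(match_alert_visits(alerts_at([100]), visits_at([129]))) == 0

    def test_visit_at_window_edge_matched(self):
        m = match_alert_visits(alerts_at([100]), visits_at([128]))
        assert len(m) == 1
        assert m.iloc[0]["week_bin"] == 4

    def test_visit_before_alert_never_matched(self):
        assert len(match_alert_visits(alerts_at([100]), visits_at([95]))) == 0

    def test_same_day_visit_counts_in_week_one(self):
        m = match_alert_visits(alerts_at([100]), visits_at([100]))
        assert len(m) == 1
        assert m.iloc[0]["lag_days"] == 0
        assert m.iloc[0]["week_bin"] == 1

    def test_one_to_one_with_multiple_alerts(self):
        # two alerts, one visit: only the earlier alert is discharged
        m = match_alert_visits(alerts_at([100, 105]), visits_at([106]))
        assert len(m) == 1
        assert m.iloc[0]["alert_id"] == 0

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigurationError):
            match_alert_visits(alerts_at([1]), visits_at([2]), window_days=-1)

    def test_dogs_do_not_share_visits(self):
        a = pd.concat([alerts_at([100], dog="d1"), alerts_at([100], dog="d2")])
        a["alert_id"] = [0, 1]
        m = match_alert_visits(a, visits_at([105], dog="d2"))
        assert list(m["dog_id"]) == ["d2"]

    @settings(max_examples=60, deadline=None)
    @given(
        alert_days=st.lists(st.integers(0, 80), min_size=0, max_size=15),
        visit_days=st.lists(st.integers(0, 80), min_size=0, max_size=10),
        window=st.integers(0, 28),
    )
    def test_one_to_one_and_window_invariants(self, alert_days, visit_days, window):
        a = alerts_at(sorted(alert_days))
        v = visits_at(sorted(visit_days))
        m = match_alert_visits(a, v, window_days=window)
        assert m["alert_id"].is_unique and m["visit_id"].is_unique
        assert len(m) <= min(len(a), len(v))
        assert ((m["lag_days"] >= 0) & (m["lag_days"] <= window)).all()
        # shrinking the window never increases the number of matches
        m_small = match_alert_visits(a, v, window_days=max(window - 7, 0))
        assert len(m_small) <= len(m)


class TestSubgroups:
    BOUNDS = (pd.Timestamp("2020-01-01"), pd.Timestamp("2020-03-31"))

    @pytest.mark.parametrize("n_visits,group", [(0, 0), (1, 1), (2, 2), (3, 2), (5, 2), (6, 3), (9, 3)])
    def test_count_to_group_mapping(self, n_visits, group):
        v = visits_at(list(range(10, 10 + n_visits)))
        sg = assign_subgroups(v, self.BOUNDS, dogs=["d1"])
        assert sg.iloc[0]["group"] == group

    def test_non_dermatitis_visits_do_not_count(self):
        v = visits_at([10, 11, 12], derm=False)
        sg = assign_subgroups(v, self.BOUNDS, dogs=["d1"])
        assert sg.iloc[0]["group"] == 0

    def test_second_period_visits_do_not_count(self):
        v = visits_at([120, 121])  # after the period-1 end
        sg = assign_subgroups(v, self.BOUNDS, dogs=["d1"])
        assert sg.iloc[0]["group"] == 0

    def test_dog_without_visits_is_group_zero(self):
        sg = assign_subgroups(visits_at([10]), self.BOUNDS, dogs=["d1", "d2"])
        assert dict(zip(sg["dog_id"], sg["group"])) == {"d1": 1, "d2": 0}


class TestPrescriptions:
    def _rx(self, visit_ids):
        return pd.DataFrame(
            {
                "prescription_id": range(len(visit_ids)),
                "visit_id": visit_ids,
                "drug_name": "oclacitinib",
            }
        )

    def test_window_flagging(self):
        visits = visits_at([110, 160])
        flagged = attribute_prescriptions(self._rx([100, 101]), visits, alerts_at([100]))
        assert flagged["within_4wk_of_alert"].tolist() == [True, False]

    def test_all_prescriptions_at_one_visit_share_flag(self):
        visits = visits_at([110])
        flagged = attribute_prescriptions(self._rx([100, 100]), visits, alerts_at([100]))
        assert flagged["within_4wk_of_alert"].all()

    def test_orphan_prescription_rejected(self):
        with pytest.raises(InputError, match="prescription"):
            attribute_prescriptions(self._rx([999]), visits_at([110]), alerts_at([100]))


class TestWeekBins:
    def test_ceiling_arithmetic(self):
        assert list(week_bin_of_lag([3, 9, 20, 27])) == [1, 2, 3, 4]
        assert list(week_bin_of_lag([0, 7, 8, 14, 15, 21, 22, 28])) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_counts_sum_to_matches(self):
        m = match_alert_visits(alerts_at([10, 50, 90]), visits_at([13, 59, 110]))
        bins = bin_matches_by_week(m, total_visits=5)
        assert bins[[1, 2, 3, 4]].sum() == len(m)
        assert bins["outside"] == 5 - len(m)

    def test_empty_matches(self):
        m = match_alert_visits(alerts_at([]), visits_at([]))
        bins = bin_matches_by_week(m)
        assert (bins == 0).all()


class TestConservationOnCohort:
    def test_alert_and_visit_side_totals(self, medium_fit):
        res = medium_fit
        n_alerts = len(res.alerts)
        n_matched = len(res.matches)
        assert n_matched <= n_alerts
        assert res.matches["alert_id"].is_unique
        assert res.matches["visit_id"].is_unique
        assert set(res.matches["alert_id"]) <= set(res.alerts["alert_id"])
        assert set(res.matches["visit_id"]) <= set(res.visits["visit_id"])
        # visit-side: alert visits + non-alert visits = all eligible visits
        assert res.visits["is_alert_visit"].sum() == n_matched
        for p, table in res.week_tables.items():
            vp = res.visits[
                (res.visits["period"] == p)
                & res.visits["dog_id"].isin(res.eligible[p])
            ]
            assert table.loc["total"].sum() == len(vp)
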