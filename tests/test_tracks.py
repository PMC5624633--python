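"""Track splitting, the three criterion families, scores, and tuning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cpuerecon as cr
from cpuerecon.tracks import (
    EARTH_RADIUS_KM,
    DayTrack,
    forward_azimuth_deg,
    path_length_km,
)


def make_day(lats, lons, speeds=None, start="2010-05-01 00:00"):
    n = len(lats)
    ts = pd.date_range(start, periods=n, freq="1h")
    return DayTrack(
        "V0",
        ts[0].date(),
        pd.DataFrame({
            "timestamp": ts,
            "lat": lats,
            "lon": lons,
            "speed_kn": speeds if speeds is not None else np.full(n, 5.0),
        }),
    )


class TestSplitDays:
    def test_48_hourly_points_two_days(self):
        ts = pd.date_range("2010-05-01 16:00", periods=48, freq="1h")  # UTC
        pts = pd.DataFrame({
            "vessel_id": "V1", "timestamp": ts, "lat": 24.0, "lon": 122.0,
            "speed_kn": 5.0,
        })
        days = cr.split_days(pts, tz_offset_h=8)
        assert len(days) == 2
        assert all(len(d) == 24 for d in days)

    def test_too_few_points_unclassifiable(self):
        ts = pd.date_range("2010-05-01 02:00", periods=2, freq="1h")
        pts = pd.DataFrame({
            "vessel_id": "V1", "timestamp": ts, "lat": 24.0, "lon": 122.0,
            "speed_kn": 5.0,
        })
        (day,) = cr.split_days(pts)
        assert not day.classifiable

    def test_local_day_boundary(self):
        # 23:30 and 00:30 UTC fall on the same UTC+8 calendar date
        pts = pd.DataFrame({
            "vessel_id": "V1",
            "timestamp": pd.to_datetime(["2010-05-01 23:30", "2010-05-02 00:30"]),
            "lat": 24.0, "lon": 122.0, "speed_kn": 5.0,
        })
        days = cr.split_days(pts, tz_offset_h=8)
        assert len(days) == 1

    def test_unsorted_rejected(self):
        pts = pd.DataFrame({
            "vessel_id": "V1",
            "timestamp": pd.to_datetime(["2010-05-01 02:00", "2010-05-01 01:00"]),
            "lat": 24.0, "lon": 122.0, "speed_kn": 5.0,
        })
        with pytest.raises(ValueError, match="sorted"):
            cr.split_days(pts)


class TestHaversine:
    def test_identical_points(self):
        assert cr.haversine_km(24.0, 122.0, 24.0, 122.0) == 0.0

    def test_one_degree_on_equator(self):
        d = cr.haversine_km(0.0, 0.0, 0.0, 1.0)
        assert abs(d - 2 * math.pi * EARTH_RADIUS_KM / 360.0) < 0.01
        assert abs(d - 111.19) < 0.01

    def test_antipodal(self):
        d = cr.haversine_km(0.0, 0.0, 0.0, 180.0)
        assert abs(d - math.pi * EARTH_RADIUS_KM) < 0.5


class TestSpeedCriterion:
    def test_all_fast_nonfishing(self):
        day = make_day([24, 24.1, 24.2], [122, 122, 122], [8.0, 9.0, 8.0])
        assert cr.classify_speed(day, 3.0) is False

    def test_one_slow_fishing(self):
        day = make_day([24, 24.1, 24.2], [122, 122, 122], [8.0, 2.0, 7.0])
        assert cr.classify_speed(day, 3.0) is True

    def test_all_missing_unclassifiable(self):
        day = make_day([24, 24.1, 24.2], [122, 122, 122], [np.nan] * 3)
        assert cr.classify_speed(day, 3.0) is None

    def test_grid_optimum_at_retrieval_speed(self, day_tracks, track_data):
        cfg, _, labels = track_data
        best, _ = cr.grid_search(day_tracks, labels, "speed")
        assert best.threshold == math.ceil(cfg.retrieval_speed_kn)


class TestDistanceCriterion:
    def test_stationary_day_fishing(self):
        day = make_day([24.0] * 5, [122.0] * 5)
        assert cr.classify_distance(day, 130.0) is True

    def test_transit_day_nonfishing(self):
        # 24 h at 9 kn ~ 400 km of path
        lats = 20.0 + np.cumsum(np.full(24, 9 * 1.852 / 111.19))
        day = make_day(lats, [122.0] * 24)
        assert abs(path_length_km(day) - 9 * 1.852 * 23) < 4.0
        assert cr.classify_distance(day, 130.0) is False

    def test_single_point_unclassifiable(self):
        day = make_day([24.0], [122.0])
        day.classifiable = True
        assert cr.classify_distance(day, 130.0) is None

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        lats = 24.0 + np.cumsum(rng.normal(0, 0.02, size=8))
        lons = 122.0 + np.cumsum(rng.normal(0, 0.02, size=8))
        day = make_day(lats, lons)
        lo, hi = sorted(rng.uniform(10.0, 300.0, size=2))
        if cr.classify_distance(day, lo):
            assert cr.classify_distance(day, hi)


class TestResample:
    def test_hourly_day_at_5h(self):
        day = make_day(np.linspace(24, 25, 24), [122.0] * 24)
        rs = cr.resample_day(day, 5)
        hours = pd.to_datetime(rs.points["timestamp"]).dt.hour.tolist()
        assert hours == [0, 5, 10, 15, 20]

    def test_interval_one_is_identity(self):
        day = make_day(np.linspace(24, 25, 24), [122.0] * 24)
        rs = cr.resample_day(day, 1)
        assert len(rs) == 24

    def test_irregular_gaps_no_duplicates(self):
        ts = pd.to_datetime(["2010-05-01 00:00", "2010-05-01 00:30",
                             "2010-05-01 07:00", "2010-05-01 07:10"])
        day = DayTrack("V0", ts[0].date(), pd.DataFrame({
            "timestamp": ts, "lat": [24, 24.1, 24.2, 24.3],
            "lon": [122.0] * 4, "speed_kn": [5.0] * 4,
        }))
        rs = cr.resample_day(day, 5)
        assert rs.points["timestamp"].is_unique
        assert rs.points["timestamp"].is_monotonic_increasing


class TestDirectionCriterion:
    def test_straight_transit_nonfishing(self):
        lats = 20.0 + np.arange(24) * 0.15
        day = make_day(lats, [122.0] * 24)
        assert cr.classify_direction(day, 90.0, 5) is False

    def test_out_and_back_fishing(self):
        lats = np.concatenate([20.0 + np.arange(12) * 0.1,
                               21.1 - np.arange(12) * 0.1])
        day = make_day(lats, [122.0] * 24)
        assert cr.classify_direction(day, 90.0, 5) is True

    def test_within_rule_flips(self):
        lats = 20.0 + np.arange(24) * 0.15
        day = make_day(lats, [122.0] * 24)
        assert cr.classify_direction(day, 90.0, 5, rule="within") is True

    def test_too_few_points_unclassifiable(self):
        day = make_day([24.0, 24.1], [122.0, 122.0])
        assert cr.classify_direction(day, 90.0, 5) is None


class TestConfusionStats:
    # printed confusion-matrix rows for the three optimal criteria
    @pytest.mark.parametrize(
        "tp,fn,fp,tn,tpr,tnr,sss,dss",
        [
            (2731, 96, 1031, 136, 0.966, 0.117, 1.083, 0.850),   # 3 knots
            (2482, 343, 690, 474, 0.879, 0.407, 1.286, 0.471),   # 130 km
            (2687, 202, 342, 841, 0.930, 0.711, 1.641, 0.219),   # 90 deg / 5 h
        ],
    )
    def test_published_rows_reproduced(self, tp, fn, fp, tn, tpr, tnr, sss, dss):
        cs = cr.ConfusionStats(TP=tp, FN=fn, FP=fp, TN=tn)
        assert round(cs.TPR, 3) == tpr
        assert round(cs.TNR, 3) == tnr
        assert round(cs.SSS, 3) == sss
        assert round(cs.DSS, 3) == dss

    def test_perfect_prediction(self):
        cs = cr.confusion_stats([True, False, True], [True, False, True])
        assert cs.SSS == 2.0 and cs.DSS == 0.0

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cr.confusion_stats([True, True], [True, True])

    @given(st.integers(1, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=200, deadline=None)
    def test_identities_hold(self, tp, fn, fp, tn):
        cs = cr.ConfusionStats(TP=tp, FN=fn, FP=fp, TN=tn)
        assert cs.TPR == tp / (tp + fn)
        assert cs.TNR == tn / (tn + fp)
        assert math.isclose(cs.SSS, cs.TPR + cs.TNR)
        assert math.isclose(cs.DSS, abs(cs.TPR - cs.TNR))
        assert 0.0 <= cs.SSS <= 2.0
        assert 0.0 <= cs.DSS <= 1.0


class TestGridSearch:
    def test_single_cell_grid(self, day_tracks, track_data):
        _, _, labels = track_data
        best, table = cr.grid_search(day_tracks, labels, "speed", thresholds=[3.0])
        assert best.threshold == 3.0
        assert len(table) == 1

    def test_tie_broken_by_dss(self):
        table = pd.DataFrame({
            "threshold": [1.0, 2.0], "interval_h": [1, 1],
            "SSS": [1.50, 1.499], "DSS": [0.3, 0.1],
        })
        tied = table[table["SSS"] >= table["SSS"].max() - 0.01]
        assert tied.sort_values("DSS").iloc[0]["threshold"] == 2.0

    def test_best_cell_never_dominated(self, day_tracks, track_data):
        _, _, labels = track_data
        for approach in ("speed", "distance"):
            best, table = cr.grid_search(day_tracks, labels, approach)
            row = table[table["threshold"] == best.threshold].iloc[0]
            dominating = table[(table["SSS"] > row["SSS"]) & (table["DSS"] < row["DSS"])]
            assert len(dominating) == 0


class TestApplyCriterion:
    def test_empty_input(self):
        out = cr.apply_criterion([], cr.CriterionSpec("speed", 3.0))
        assert len(out) == 0

    def test_pure_function(self, day_tracks):
        spec = cr.CriterionSpec("direction", 90.0, 5)
        a = cr.apply_criterion(day_tracks[:50], spec)
        b = cr.apply_criterion(day_tracks[:50], spec)
        pd.testing.assert_frame_equal(a, b)

    def test_direction_sensitivity_on_synthetic_fleet(self, day_tracks, track_data):
        _, _, labels = track_data
        spec = cr.CriterionSpec("direction", 90.0, 5)
        pred = cr.apply_criterion(day_tracks, spec)
        m = pred.merge(labels, on=["vessel_id", "date"])
        cs = cr.confusion_stats(m["is_fishing_x"].astype(bool), m["is_fishing_y"])
        assert cs.TPR >= 0.9

    def test_unknown_approach_rejected(self):
        with pytest.raises(ValueError):
            cr.CriterionSpec("sonar", 3.0)
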