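"""Cleaning-stage behaviour: speed filter, land handling, trips, moult,
day counting, inclusion rule and daily regularization."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from trackiba.geo import AzimuthalEquidistant, great_circle_distance, path_length
from trackiba.preprocess import (detect_moult, flag_land, preprocess_track,
                                 regularize_daily, select_tracks, speed_filter,
                                 split_trips, tracking_days)
from trackiba.simulate import demo_config, simulate_dataset

COAST = box(10.0, -33.3, 26.0, -30.0)   # land north of -33.3
PROJ = AzimuthalEquidistant(18.0, -33.5)


def _frame(times, lon, lat, on_land=None, iid="b1"):
    df = pd.DataFrame({
        "individual_id": iid,
        "timestamp": pd.to_datetime(times, utc=True),
        "lon": lon, "lat": lat,
        "colony": "Isle A", "stage": "pre_moult", "year": 2018,
        "device": "GPS-GSM"})
    if on_land is not None:
        df["on_land"] = on_land
    return df


class TestSpeedFilter:
    def test_clean_track_unchanged(self):
        times = pd.date_range("2018-09-01", periods=10, freq="h", tz="UTC")
        df = _frame(times, 18.0 + 0.01 * np.arange(10), [-34.0] * 10)
        out, removed = speed_filter(df)
        assert removed.empty
        pd.testing.assert_frame_equal(out, df)

    def test_injected_teleport_removed_exactly(self):
        times = pd.date_range("2018-09-01", periods=10, freq="h", tz="UTC")
        lon = 18.0 + 0.01 * np.arange(10.0)
        lon[5] += 3.0  # ~280 km sideways for one hour
        df = _frame(times, lon, [-34.0] * 10)
        out, removed = speed_filter(df)
        assert list(removed["timestamp"]) == [times[5]]
        assert len(out) == 9

    def test_filter_is_idempotent_on_simulated_tracks(self):
        ts, _ = simulate_dataset(demo_config(seed=2))
        for iid in ts.ids[:6]:
            once, _ = speed_filter(ts.get(iid))
            twice, removed2 = speed_filter(once)
            assert removed2.empty
            pd.testing.assert_frame_equal(once, twice)

    def test_degenerate_track_dropped_with_warning(self):
        times = pd.date_range("2018-09-01", periods=2, freq="h", tz="UTC")
        df = _frame(times, [18.0, 21.0], [-34.0, -34.0])
        with pytest.warns(UserWarning, match="degenerate"):
            out, _ = speed_filter(df)
        assert out.empty


class TestFlagLand:
    def test_colony_fix_flagged(self):
        df = _frame(["2018-09-01T06:00Z"], [18.0], [-34.0])
        out = flag_land(df, COAST, [(18.0, -34.0)])
        assert out["on_land"].all()

    def test_offshore_fix_at_sea(self):
        df = _frame(["2018-09-01T06:00Z"], [18.0], [-34.5])
        out = flag_land(df, COAST, [(18.0, -33.3)])
        assert not out["on_land"].any()

    def test_inside_land_polygon_flagged(self):
        df = _frame(["2018-09-01T06:00Z"], [18.0], [-32.0])
        out = flag_land(df, COAST, [])
        assert out["on_land"].all()

    def test_missing_coastline_errors(self):
        df = _frame(["2018-09-01T06:00Z"], [18.0], [-34.0])
        with pytest.raises(ValueError, match="coastline"):
            flag_land(df, None, [])


class TestSplitTrips:
    @pytest.mark.parametrize("pattern,n_trips", [
        ([False, False, True, False, False], 2),   # sea-land-sea
        ([False] * 5, 1),                          # no land
        ([True] * 5, 0),                           # land only
    ])
    def test_patterns(self, pattern, n_trips):
        times = pd.date_range("2018-09-01", periods=len(pattern), freq="h",
                              tz="UTC")
        df = _frame(times, [18.0] * len(pattern), [-34.0] * len(pattern),
                    on_land=pattern)
        trips, _ = split_trips(df)
        assert len(trips) == n_trips

    def test_trips_partition_at_sea_fixes(self):
        pattern = [False, False, True, False, True, True, False, False, False]
        times = pd.date_range("2018-09-01", periods=len(pattern), freq="h",
                              tz="UTC")
        df = _frame(times, 18.0 + 0.01 * np.arange(len(pattern)),
                    [-34.0] * len(pattern), on_land=pattern)
        trips, _ = split_trips(df, min_fixes=1)
        got = pd.concat([t.fixes for t in trips])
        expect = df[~df["on_land"]]
        assert sorted(got["timestamp"]) == list(expect["timestamp"])


class TestDetectMoult:
    def _track_with_land_run(self, hours_ashore):
        sea1 = [False] * 5
        land = [True] * (hours_ashore + 1)  # hourly fixes spanning hours_ashore
        times = pd.date_range("2018-09-01", periods=len(sea1) + len(land),
                              freq="h", tz="UTC")
        n = len(times)
        return _frame(times, [18.0] * n, [-34.0] * n, on_land=sea1 + land)

    def test_60h_ashore_detected(self):
        m = detect_moult(self._track_with_land_run(60))
        assert m is not None and m.duration_h == 60

    def test_40h_ashore_not_moult(self):
        assert detect_moult(self._track_with_land_run(40)) is None

    def test_exactly_48h_not_moult(self):
        # strict inequality: > 48 h on land
        assert detect_moult(self._track_with_land_run(48)) is None

    def test_nightly_roosts_broken_by_sea_fixes(self):
        # night-only style sampling: ashore every night, at sea every day
        times, land = [], []
        for d in range(1, 5):
            times += [f"2018-09-0{d}T09:00Z", f"2018-09-0{d}T21:00Z"]
            land += [False, True]
        df = _frame(times, [18.0] * 8, [-34.0] * 8, on_land=land)
        assert detect_moult(df) is None

    def test_nearest_colony_reported(self):
        m = detect_moult(self._track_with_land_run(60),
                         colony_positions={"A": (18.0, -34.0),
                                           "B": (21.0, -34.0)})
        assert m.colony == "A"


class TestTrackingDays:
    def test_full_span(self):
        # 2018-09-01T00:00 .. 2018-09-22T23:00: Sep 2..21 are full dates
        times = pd.date_range("2018-09-01T06:00", "2018-09-22T23:00",
                              freq="h", tz="UTC")
        n = len(times)
        df = _frame(times, [18.0] * n, [-34.0] * n, on_land=[False] * n)
        assert tracking_days(df) == 20

    def test_single_day_track(self):
        times = pd.date_range("2018-09-01T06:00", periods=10, freq="h",
                              tz="UTC")
        df = _frame(times, [18.0] * 10, [-34.0] * 10, on_land=[False] * 10)
        assert tracking_days(df) <= 1

    def test_counts_to_last_sea_fix_before_moult(self):
        sea = pd.date_range("2018-09-01T00:00", "2018-09-25T23:00", freq="h",
                            tz="UTC")
        land = pd.date_range("2018-09-26T00:00", "2018-09-29T00:00", freq="h",
                             tz="UTC")
        times = sea.append(land)
        flags = [False] * len(sea) + [True] * len(land)
        df = _frame(times, [18.0] * len(times), [-34.0] * len(times),
                    on_land=flags)
        m = detect_moult(df)
        assert m is not None
        # last sea fix 25 Sep 23:00 -> full dates Sep 1..24 inclusive = 24,
        # the land days of the haul-out do not count
        assert tracking_days(df, m) == 24


class TestSelectTracks:
    def test_strict_20_day_rule(self, small_dataset):
        ts, _ = small_dataset
        n_days = {iid: 20 for iid in ts.ids}
        n_days[ts.ids[0]] = 21
        selected, excluded = select_tracks(ts, n_days, min_days=20)
        assert selected.ids == [ts.ids[0]]
        assert set(excluded) == set(ts.ids[1:])


class TestRegularizeDaily:
    def _hourly_track(self, days=10):
        times = pd.date_range("2018-09-01T05:00", periods=days * 24, freq="h",
                              tz="UTC")
        rng = np.random.default_rng(5)
        lon = 18.0 + np.cumsum(rng.normal(0, 0.01, len(times)))
        lat = -34.0 + np.cumsum(rng.normal(0, 0.01, len(times)))
        n = len(times)
        return _frame(times, lon, lat, on_land=[False] * n)

    def test_one_position_per_calendar_day(self):
        track = self._hourly_track(10)  # spans 11 calendar dates
        daily = regularize_daily(track, PROJ)
        assert len(daily) == track["timestamp"].dt.date.nunique()
        assert not daily["timestamp"].dt.date.duplicated().any()
        assert (daily["timestamp"].dt.hour == 12).all()

    def test_positions_lie_on_segments(self):
        track = self._hourly_track(5)
        daily = regularize_daily(track, PROJ)
        x, y = PROJ.forward(track["lon"].to_numpy(), track["lat"].to_numpy())
        dx, dy = PROJ.forward(daily["lon"].to_numpy(), daily["lat"].to_numpy())
        t = track["timestamp"].astype("int64").to_numpy()
        for k in range(len(daily)):
            tr = daily["timestamp"].iloc[k].value
            j = np.searchsorted(t, tr)
            if 0 < j < len(t):
                w = (tr - t[j - 1]) / (t[j] - t[j - 1])
                assert dx[k] == pytest.approx(x[j - 1] + w * (x[j] - x[j - 1]),
                                              abs=1e-6)
                assert dy[k] == pytest.approx(y[j - 1] + w * (y[j] - y[j - 1]),
                                              abs=1e-6)

    def test_daily_path_not_longer_than_hourly(self):
        track = self._hourly_track(15)
        daily = regularize_daily(track, PROJ)
        assert (path_length(daily["lon"], daily["lat"])
                <= path_length(track["lon"], track["lat"]))

    def test_reregularization_is_identity(self):
        daily = regularize_daily(self._hourly_track(8), PROJ)
        again = regularize_daily(daily, PROJ)
        np.testing.assert_allclose(again["lon"], daily["lon"], atol=1e-9)
        np.testing.assert_allclose(again["lat"], daily["lat"], atol=1e-9)

    def test_long_gap_flagged_not_interpolated(self):
        track = self._hourly_track(12)
        mask = ~track["timestamp"].dt.day.isin([4, 5, 6, 7])
        daily = regularize_daily(track[mask].reset_index(drop=True), PROJ)
        assert daily["gap"].sum() >= 3
        assert daily.loc[daily["gap"], "lon"].isna().all()

    def test_degenerate_single_day_dropped(self):
        track = self._hourly_track(10).iloc[:12]
        assert regularize_daily(track, PROJ).empty


def test_preprocess_track_end_to_end():
    ts, truths = simulate_dataset(demo_config(seed=17))
    iid = next(i for i in ts.ids if truths[i].moult_interval is not None)
    cfg = demo_config(seed=17)
    from trackiba.simulate import make_toy_layers
    layers = make_toy_layers(cfg)
    ct = preprocess_track(ts.get(iid), layers.coastline,
                          {c.name: (c.lon, c.lat) for c in cfg.colonies},
                          PROJ)
    assert ct.moult is not None
    assert ct.n_days > 0
    assert not ct.daily.empty
    # daily track stops before the moult haul-out
    assert ct.daily["timestamp"].iloc[-1] < ct.moult.start + pd.Timedelta("1D")
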