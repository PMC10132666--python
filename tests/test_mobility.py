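import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import geomob as g
from geomob.mobility import place_centroids
from conftest import make_points

DEG_M = 111_195.0  # meters per degree of latitude on the reference sphere


class TestHaversine:
    def test_identical_points_zero(self):
        assert g.haversine_m(51.5, -0.1, 51.5, -0.1) == 0.0

    def test_one_degree_meridian_arc(self):
        """(0,0)-(0,1 deg) is 2*pi*R/360 within a meter."""
        assert g.haversine_m(0.0, 0.0, 0.0, 1.0) == pytest.approx(111_195.0, abs=1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        lat1=st.floats(-89, 89), lon1=st.floats(-179, 179),
        lat2=st.floats(-89, 89), lon2=st.floats(-179, 179),
    )
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        assert g.haversine_m(lat1, lon1, lat2, lon2) == pytest.approx(
            g.haversine_m(lat2, lon2, lat1, lon1), rel=1e-12, abs=1e-9
        )

    def test_vectorized_matches_scalar(self, rng):
        lat1, lon1, lat2, lon2 = (rng.uniform(-80, 80, 20) for _ in range(4))
        vec = g.haversine_m(lat1, lon1, lat2, lon2)
        for i in range(20):
            assert vec[i] == pytest.approx(g.haversine_m(lat1[i], lon1[i], lat2[i], lon2[i]))


def _brute_components(lat, lon, radius_m):
    """Independent oracle: connected components by repeated expansion."""
    n = len(lat)
    labels = [-1] * n
    nxt = 0
    for s in range(n):
        if labels[s] != -1:
            continue
        stack = [s]
        labels[s] = nxt
        while stack:
            i = stack.pop()
            for j in range(n):
                if labels[j] == -1 and g.haversine_m(lat[i], lon[i], lat[j], lon[j]) <= radius_m:
                    labels[j] = nxt
                    stack.append(j)
        nxt += 1
    return np.array(labels)


def _same_partition(a, b):
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


class TestDetectPlaces:
    def test_two_distant_points_two_places(self):
        lat = np.array([51.5, 51.5 + 600 / DEG_M])
        lab = g.detect_places(lat, np.array([-0.1, -0.1]))
        assert len(set(lab)) == 2

    def test_chain_linkage_single_place(self):
        """Points at 0/400/800 m along a meridian chain into one place."""
        lat = 51.5 + np.array([0.0, 400.0, 800.0]) / DEG_M
        lab = g.detect_places(lat, np.full(3, -0.1))
        assert len(set(lab)) == 1

    def test_jittered_cloud_one_place_centroid_inside(self, rng):
        base = np.array([51.5, -0.1])
        off = rng.uniform(-100, 100, (20, 2)) / DEG_M
        lat, lon = base[0] + off[:, 0], base[1] + off[:, 1]
        lab = g.detect_places(lat, lon)
        assert len(set(lab)) == 1
        cent = place_centroids(lat, lon, lab)
        d = g.haversine_m(cent.iloc[0]["lat"], cent.iloc[0]["lon"], base[0], base[1])
        assert d < 150  # inside the jitter disc

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        lat = 51.5 + rng.uniform(0, 2500, n) / DEG_M
        lon = -0.1 + rng.uniform(0, 2500, n) / DEG_M
        ours = g.detect_places(lat, lon, radius_m=500)
        oracle = _brute_components(lat, lon, 500)
        assert _same_partition(ours, oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn_dbscan(self, seed):
        """Cross-check against DBSCAN with haversine metric (minPt=1)."""
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(seed)
        n = 40
        lat = 51.5 + rng.uniform(0, 3000, n) / DEG_M
        lon = -0.1 + rng.uniform(0, 3000, n) / DEG_M
        ours = g.detect_places(lat, lon, radius_m=500)
        ref = DBSCAN(
            eps=500 / 6_371_000, min_samples=1, metric="haversine", algorithm="ball_tree"
        ).fit_predict(np.radians(np.column_stack([lat, lon])))
        assert _same_partition(ours, ref)

    def test_cross_place_separation_invariant(self, rng):
        """Any two points in different places are > radius apart."""
        n = 25
        lat = 51.5 + rng.uniform(0, 2000, n) / DEG_M
        lon = -0.1 + rng.uniform(0, 2000, n) / DEG_M
        lab = g.detect_places(lat, lon, radius_m=500)
        for i in range(n):
            for j in range(i + 1, n):
                if lab[i] != lab[j]:
                    assert g.haversine_m(lat[i], lon[i], lat[j], lon[j]) > 500


class TestExtractDailyTrips:
    def test_back_and_forth_two_trips(self):
        """P1 09:00 -> P2 12:00 -> P1 18:00 yields P1->P2 and P2->P1."""
        p1, p2 = (51.5, -0.1), (51.5 + 1000 / DEG_M, -0.1)
        pts = make_points(
            [
                ("u", "2020-06-01T09:00:00Z", *p1),
                ("u", "2020-06-01T12:00:00Z", *p2),
                ("u", "2020-06-01T18:00:00Z", *p1),
            ]
        )
        trips = g.extract_daily_trips(pts)
        assert len(trips) == 2
        assert trips["distance_m"].iloc[0] == pytest.approx(1000, rel=0.01)
        # second trip reverses the first
        assert trips.iloc[0]["origin_lat"] == trips.iloc[1]["dest_lat"]

    def test_same_building_no_trip(self):
        pts = make_points(
            [
                ("u", "2020-06-01T09:00:00Z", 51.5, -0.1),
                ("u", "2020-06-01T10:00:00Z", 51.5 + 80 / DEG_M, -0.1),
            ]
        )
        assert g.extract_daily_trips(pts).empty

    def test_cross_midnight_dropped(self):
        """23:00 day 1 to 01:00 day 2 is not a daily trip (calendar-day rule)."""
        pts = make_points(
            [
                ("u", "2020-06-01T22:00:00Z", 51.5, -0.1),  # 23:00 London (BST)
                ("u", "2020-06-02T00:00:00Z", 51.6, -0.1),  # 01:00 next day
            ]
        )
        assert g.extract_daily_trips(pts, day_tz="Europe/London").empty

    def test_trip_conservation(self, small_stream):
        """Total trips equal the place-change count over user-days."""
        pts = small_stream["points"]
        trips = g.extract_daily_trips(pts)
        expected = 0
        work = pts.copy()
        work["date"] = pd.to_datetime(work["timestamp"], utc=True).dt.tz_convert(
            "Europe/London"
        ).dt.date
        for _, grp in work.sort_values("timestamp").groupby(["user_id", "date"]):
            if len(grp) < 2:
                continue
            lab = g.detect_places(grp["lat"].to_numpy(), grp["lon"].to_numpy())
            expected += int((np.diff(lab) != 0).sum())
        assert len(trips) == expected


class TestDailyIndices:
    def test_m_rate_simple_ratio(self):
        rows = []
        for u in range(10):
            rows.append((f"u{u}", "2020-06-01T10:00:00Z", 51.5, -0.1 + u * 1e-5))
        pts = make_points(rows)
        d = pd.Timestamp("2020-06-01").date()
        trips = pd.DataFrame(
            {
                "user_id": ["u0", "u1", "u2"],
                "date": [d] * 3,
                "origin_lat": 51.5, "origin_lon": -0.1,
                "dest_lat": 51.51, "dest_lon": -0.1,
                "distance_m": [1000.0, 2000.0, 3000.0],
            }
        )
        daily = g.daily_indices(trips, pts)
        assert daily.loc[0, "m_rate"] == pytest.approx(0.3)

    def test_avg_dis_is_user_weighted(self):
        """One mover with 1000m+3000m trips averages to 2000m; two movers
        with per-user means 1000 and 3000 also average to 2000m."""
        d = pd.Timestamp("2020-06-01").date()
        pts = make_points(
            [("a", "2020-06-01T10:00:00Z", 51.5, -0.1), ("b", "2020-06-01T10:00:00Z", 51.5, -0.2)]
        )
        one = pd.DataFrame(
            {"user_id": ["a", "a"], "date": [d, d],
             "origin_lat": 0.0, "origin_lon": 0.0, "dest_lat": 0.0, "dest_lon": 0.0,
             "distance_m": [1000.0, 3000.0]}
        )
        assert g.daily_indices(one, pts).loc[0, "avg_dis_m"] == pytest.approx(2000.0)
        two = pd.DataFrame(
            {"user_id": ["a", "a", "a", "b"], "date": [d] * 4,
             "origin_lat": 0.0, "origin_lon": 0.0, "dest_lat": 0.0, "dest_lon": 0.0,
             "distance_m": [1000.0, 1000.0, 1000.0, 3000.0]}
        )
        # trip-weighted mean would be 1500; user-weighted is 2000
        assert g.daily_indices(two, pts).loc[0, "avg_dis_m"] == pytest.approx(2000.0)

    def test_no_movers_day_has_nan_distance(self):
        pts = make_points([("a", "2020-06-01T10:00:00Z", 51.5, -0.1)])
        daily = g.daily_indices(pd.DataFrame(columns=["user_id", "date", "distance_m"]), pts)
        assert daily.loc[0, "m_rate"] == 0.0
        assert np.isnan(daily.loc[0, "avg_dis_m"])

    def test_annual_ratio_of_means_convention(self):
        """The summary reproduces a ratio from daily means: with mean
        daily movers 120.58 over mean daily users 1653 the annual
        ratio rounds to 0.073."""
        daily = pd.DataFrame(
            {
                "date": pd.date_range("2019-01-01", periods=2),
                "n_users": [1653, 1653],
                "n_movers": [120, 121.16],
                "m_rate": [120 / 1653, 121.16 / 1653],
                "avg_dis_m": [5426.56, 5426.56],
            }
        )
        s = g.summarize_indices(daily)
        assert s["mean_daily_movers"] == pytest.approx(120.58)
        assert round(s["ratio_of_means"], 3) == 0.073


class TestDecompose:
    def test_constant_series_zero_seasonal_residual(self):
        s = pd.Series(5.0, index=pd.date_range("2020-01-01", periods=28))
        res = g.decompose_series(s, period=7)
        assert np.allclose(res.seasonal, 0.0, atol=1e-12)
        assert np.allclose(res.residual.dropna(), 0.0, atol=1e-12)

    def test_recovers_planted_weekly_pattern(self):
        """Linear trend + fixed weekly pattern, no noise: the seasonal
        component equals the pattern away from the edges."""
        n = 70
        idx = pd.date_range("2020-01-06", periods=n)  # starts a Monday
        pattern = np.array([3.0, 1.0, 0.0, -1.0, -2.0, 0.5, -1.5])
        pattern -= pattern.mean()
        values = 0.1 * np.arange(n) + pattern[np.arange(n) % 7]
        res = g.decompose_series(pd.Series(values, index=idx), period=7)
        core = res.seasonal.iloc[7:-7].to_numpy()
        expect = pattern[np.arange(7, n - 7) % 7]
        assert np.max(np.abs(core - expect)) < 1e-9

    def test_additive_identity(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=35), index=pd.date_range("2020-01-01", periods=35))
        res = g.decompose_series(s, period=7)
        recon = res.trend + res.seasonal + res.residual
        mask = res.trend.notna()
        assert np.allclose(recon[mask], s[mask], atol=1e-12)

    def test_too_short_series_rejected(self):
        s = pd.Series(range(10), index=pd.date_range("2020-01-01", periods=10))
        with pytest.raises(ValueError):
            g.decompose_series(s, period=7)
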