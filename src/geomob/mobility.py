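"""Place detection, daily-trip extraction and global mobility indices.

A *place* is a density cluster of one user's nearby points: geotagged
posts carry coordinate jitter (same building, same park), so raw points
are grouped with a 500 m linkage radius before any displacement counts
as travel.  A *daily trip* is a displacement between two distinct places
by one user within one local calendar day.  Two global indices summarise
the trip stream per day:

``m_rate``
    fraction of users active that day who made at least one trip — how
    actively people are making journeys;
``avg_dis``
    mean over movers of each mover's mean crow-fly trip distance that
    day (user-weighted, not trip-weighted) — a proxy for the extent of
    activity space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

EARTH_RADIUS_M = 6_371_000.0

DEFAULT_RADIUS_M = 500.0
DEFAULT_MIN_PTS = 1
DEFAULT_DAY_TZ = "Europe/London"


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters on a 6,371,000 m sphere.

    Accepts scalars or arrays (broadcast elementwise).
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.shape else float(d)


def detect_places(
    lat: np.ndarray,
    lon: np.ndarray,
    radius_m: float = DEFAULT_RADIUS_M,
    min_pts: int = DEFAULT_MIN_PTS,
) -> np.ndarray:
    """Cluster points into places; returns an integer label per point.

    Density-based clustering with the haversine metric.  With
    ``min_pts=1`` every point is a core point, so the clusters are
    exactly the connected components of the graph linking point pairs
    within ``radius_m`` — computed directly as such.  For ``min_pts>1``
    sklearn's DBSCAN is used (noise points get singleton labels, since
    a lone post is still a visited place for trip extraction).

    Labels are renumbered by order of first appearance, so they are
    deterministic given point order.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    n = lat.size
    if n == 0:
        raise ValueError("detect_places requires at least one point")
    if n == 1:
        return np.zeros(1, dtype=int)
    if min_pts <= 1:
        ii, jj = np.triu_indices(n, k=1)
        d = haversine_m(lat[ii], lon[ii], lat[jj], lon[jj])
        keep = d <= radius_m
        graph = coo_matrix(
            (np.ones(keep.sum()), (ii[keep], jj[keep])), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        from sklearn.cluster import DBSCAN

        X = np.radians(np.column_stack([lat, lon]))
        labels = DBSCAN(
            eps=radius_m / EARTH_RADIUS_M,
            min_samples=min_pts,
            metric="haversine",
            algorithm="ball_tree",
        ).fit_predict(X)
        # noise points become their own singleton places
        noise = labels == -1
        if noise.any():
            start = labels.max() + 1
            labels = labels.copy()
            labels[noise] = np.arange(start, start + noise.sum())
    # renumber by first appearance for determinism
    _, first_pos, inv = np.unique(labels, return_index=True, return_inverse=True)
    rank = np.argsort(np.argsort(first_pos))
    return rank[inv]


def place_centroids(lat: np.ndarray, lon: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Arithmetic-mean centroid per place label."""
    df = pd.DataFrame({"label": labels, "lat": lat, "lon": lon})
    cent = df.groupby("label", sort=True)[["lat", "lon"]].mean()
    cent.index.name = "place_id"
    return cent


def local_dates(timestamps: pd.Series, day_tz: str = DEFAULT_DAY_TZ) -> pd.Series:
    """Local civil date of each UTC timestamp under ``day_tz``."""
    ts = pd.to_datetime(timestamps, utc=True)
    return ts.dt.tz_convert(day_tz).dt.date


def extract_daily_trips(
    points: pd.DataFrame,
    radius_m: float = DEFAULT_RADIUS_M,
    min_pts: int = DEFAULT_MIN_PTS,
    day_tz: str = DEFAULT_DAY_TZ,
    scope: str = "per-user-day",
) -> pd.DataFrame:
    """Extract daily trips from a cleaned point table.

    For every (user, local calendar day): cluster that scope's points
    into places, order points chronologically, and emit one trip per
    consecutive pair of points assigned to different places.  Trip
    distance is the haversine distance between place centroids.
    Cross-midnight displacements are dropped by construction.

    ``scope`` may be ``"per-user-day"`` (default; clustering runs on
    each user-day's points) or ``"per-user"`` (one clustering per user
    over the whole period, days partition the trip sequence).

    Returns columns ``user_id, date, origin_lat, origin_lon, dest_lat,
    dest_lon, distance_m``.
    """
    if scope not in ("per-user-day", "per-user"):
        raise ValueError(f"unknown clustering scope {scope!r}")
    cols = ["user_id", "date", "origin_lat", "origin_lon", "dest_lat", "dest_lon", "distance_m"]
    if points.empty:
        return pd.DataFrame(columns=cols)
    pts = points.copy()
    pts["timestamp"] = pd.to_datetime(pts["timestamp"], utc=True)
    pts["date"] = local_dates(pts["timestamp"], day_tz)
    pts = pts.sort_values(["user_id", "timestamp"], kind="mergesort")

    group_keys = ["user_id"] if scope == "per-user" else ["user_id", "date"]
    out: list[tuple] = []
    for key, g in pts.groupby(group_keys, sort=True):
        lat = g["lat"].to_numpy()
        lon = g["lon"].to_numpy()
        if len(g) < 2:
            continue
        labels = detect_places(lat, lon, radius_m=radius_m, min_pts=min_pts)
        if labels.max() == 0:
            continue
        cent = place_centroids(lat, lon, labels)
        dates = g["date"].to_numpy()
        for k in range(len(g) - 1):
            if labels[k] == labels[k + 1] or dates[k] != dates[k + 1]:
                continue
            o = cent.loc[labels[k]]
            d = cent.loc[labels[k + 1]]
            dist = haversine_m(o["lat"], o["lon"], d["lat"], d["lon"])
            user = key[0] if isinstance(key, tuple) else key
            out.append((user, dates[k], o["lat"], o["lon"], d["lat"], d["lon"], dist))
    return pd.DataFrame(out, columns=cols)


def daily_indices(
    trips: pd.DataFrame,
    points: pd.DataFrame,
    day_tz: str = DEFAULT_DAY_TZ,
) -> pd.DataFrame:
    """Per-day mobility indices from trips and the full point table.

    Returns columns ``date, n_users, n_movers, m_rate, avg_dis_m``.
    ``avg_dis_m`` is NaN on days with no movers.
    """
    pts = points.copy()
    pts["date"] = local_dates(pts["timestamp"], day_tz)
    active = pts.groupby("date")["user_id"].nunique().rename("n_users")
    if trips.empty:
        empty_idx = pd.Index([], name="date")
        movers = pd.Series(dtype=int, name="n_movers", index=empty_idx)
        avg = pd.Series(dtype=float, name="avg_dis_m", index=empty_idx)
    else:
        movers = trips.groupby("date")["user_id"].nunique().rename("n_movers")
        per_user = trips.groupby(["date", "user_id"])["distance_m"].mean()
        avg = per_user.groupby("date").mean().rename("avg_dis_m")
    out = pd.concat([active, movers, avg], axis=1).reset_index()
    out = out.sort_values("date").reset_index(drop=True)
    out["n_movers"] = out["n_movers"].fillna(0).astype(int)
    out["m_rate"] = np.where(out["n_users"] > 0, out["n_movers"] / out["n_users"], np.nan)
    return out[["date", "n_users", "n_movers", "m_rate", "avg_dis_m"]]


def summarize_indices(daily: pd.DataFrame) -> dict:
    """Annual-style summary of a daily index series.

    Reports the ratio of movers to users under both conventions found
    in practice — the ratio of daily means and the mean of daily ratios
    — since they differ on real data; the ratio-of-means convention is
    the primary one.
    """
    mean_users = float(daily["n_users"].mean())
    mean_movers = float(daily["n_movers"].mean())
    return {
        "mean_daily_users": mean_users,
        "mean_daily_movers": mean_movers,
        "ratio_of_means": mean_movers / mean_users if mean_users else float("nan"),
        "mean_of_ratios": float(daily["m_rate"].mean()),
        "mean_avg_dis_m": float(daily["avg_dis_m"].mean()),
    }


@dataclass
class DecompositionResult:
    """Classical additive decomposition of a daily series."""

    observed: pd.Series
    trend: pd.Series
    seasonal: pd.Series
    residual: pd.Series
    period: int
    model: str = "additive"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed,
                "trend": self.trend,
                "seasonal": self.seasonal,
                "residual": self.residual,
            }
        )


def decompose_series(
    series: pd.Series, period: int = 7, model: str = "additive"
) -> DecompositionResult:
    """Classical moving-average decomposition of a daily index series.

    Trend is the centred period-length moving average; the seasonal
    component is the per-position mean of the detrended series,
    re-centred to sum to zero over one period; the residual is what
    remains.  Requires at least two full periods.
    """
    from statsmodels.tsa.seasonal import seasonal_decompose

    if len(series) < 2 * period:
        raise ValueError(f"series must cover at least two periods ({2 * period} values)")
    res = seasonal_decompose(series, model=model, period=period)
    return DecompositionResult(
        observed=series,
        trend=res.trend,
        seasonal=res.seasonal,
        residual=res.resid,
        period=period,
        model=model,
    )
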