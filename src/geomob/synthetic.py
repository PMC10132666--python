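"""Synthetic study data with known ground truth.

Everything downstream — cleaning, trip extraction, indices, networks,
spatial statistics — is exercised on data generated here, so every
pipeline test is a *recovery* test: the generator emits the truth it
planted alongside the observable stream.

Three generators:

* a grid zone system standing in for census zones;
* a geo-located point stream emulating geotagged posts: users visit
  activity places drawn over the zones, movers make trips whose
  lengths follow a log-normal (median 5.4 km, matching the scale of
  observed crow-fly trip distances in a large city), points carry
  sub-place coordinate jitter and a double-peaked diurnal timestamp
  profile;
* weekly zone-level case counts with a simultaneous-autoregressive
  (SAR) spatially autocorrelated field and a controllable linear
  coupling to zone attractiveness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .mobility import haversine_m
from .spatial import SpatialWeights
from .zones import ZoneSystem, generate_zones  # noqa: F401  (re-export)

M_PER_DEG_LAT = 111_195.0  # 2*pi*R/360 on the 6,371,000 m sphere

#: morning and late-afternoon peaks, quiet overnight
DEFAULT_DIURNAL = (
    1, 1, 1, 1, 1, 2, 4, 8, 12, 10, 7, 6,
    6, 6, 7, 8, 10, 12, 10, 8, 6, 4, 3, 2,
)


@dataclass
class ActivityScenario:
    """Parameters of the synthetic activity-stream generator.

    Defaults encode the reference study conditions: 2000 users over 30
    days, 30% of user-days involving travel, log-normal trip distances
    with a 5.4 km median, 100 m coordinate jitter (well under the
    500 m place-clustering radius) and a double-peaked diurnal profile.
    """

    n_users: int = 2000
    n_days: int = 30
    start_date: date = date(2019, 1, 7)
    p_mover: float = 0.3
    trips_per_mover_day: float = 1.5  # mean of 1 + Poisson(mean - 1)
    trip_distance_median_m: float = 5400.0
    trip_distance_sigma: float = 0.5  # log-scale dispersion
    jitter_m: float = 100.0
    points_per_visit: float = 1.3  # mean of 1 + Poisson(mean - 1)
    diurnal_weights: tuple = DEFAULT_DIURNAL
    place_intensity: str = "centre"  # or "uniform"
    seed: int = 0

    def validate(self, radius_m: float = 500.0) -> None:
        if not 0.0 <= self.p_mover <= 1.0:
            raise ValueError("p_mover must be a probability")
        if self.jitter_m >= radius_m:
            raise ValueError(
                f"jitter_m={self.jitter_m} must be below the place-clustering "
                f"radius {radius_m}; larger jitter corrupts place recovery"
            )
        if len(self.diurnal_weights) != 24 or min(self.diurnal_weights) < 0:
            raise ValueError("diurnal_weights must be 24 non-negative values")
        if sum(self.diurnal_weights) <= 0:
            raise ValueError("diurnal_weights must have positive sum")
        if self.trips_per_mover_day < 1:
            raise ValueError("movers make at least one trip per mover day")


def _sample_places(
    zones: ZoneSystem, n: int, intensity: str, rng: np.random.Generator
) -> np.ndarray:
    """(lat, lon) array of candidate activity places inside the zones."""
    min_lon, min_lat, max_lon, max_lat = zones.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = (n - got) * 2 + 8
        if intensity == "uniform":
            lat = rng.uniform(min_lat, max_lat, m)
            lon = rng.uniform(min_lon, max_lon, m)
        elif intensity == "centre":
            clat, clon = (min_lat + max_lat) / 2, (min_lon + max_lon) / 2
            lat = rng.normal(clat, (max_lat - min_lat) / 5, m)
            lon = rng.normal(clon, (max_lon - min_lon) / 5, m)
        else:
            raise ValueError(f"unknown place_intensity {intensity!r}")
        inside = zones.locate(lat, lon) >= 0
        take = min(int(inside.sum()), n - got)
        sel = np.flatnonzero(inside)[:take]
        out[got : got + take, 0] = lat[sel]
        out[got : got + take, 1] = lon[sel]
        got += take
    return out


def _step(lat: float, lon: float, dist_m: float, bearing: float) -> tuple[float, float]:
    dlat = dist_m * math.cos(bearing) / M_PER_DEG_LAT
    dlon = dist_m * math.sin(bearing) / (M_PER_DEG_LAT * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def generate_activity_stream(
    zones: ZoneSystem,
    scenario: ActivityScenario,
    radius_m: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a geo-located point stream with ground truth.

    Every user posts every day.  On a mover user-day the user starts at
    their home place and makes ``1 + Poisson`` trips; each destination
    lies at a log-normal distance (truncated below at ``1.2 * radius_m``
    so places stay distinguishable after clustering) in a direction
    kept inside the zone system.  Each visited place emits one or more
    points jittered within ``jitter_m`` of the true place; timestamps
    are drawn from the diurnal profile and assigned to the visit
    sequence in chronological order.

    Returns ``(points, truth_trips, truth_user_days)``:

    * points: ``user_id, timestamp, lat, lon`` (UTC ISO instants);
    * truth_trips: one row per planted trip with true place coordinates
      and true crow-fly distance;
    * truth_user_days: ``user_id, date, is_mover, n_trips``.
    """
    scenario.validate(radius_m)
    rng = np.random.default_rng(scenario.seed)
    min_lon, min_lat, max_lon, max_lat = zones.bounds
    clat, clon = (min_lat + max_lat) / 2, (min_lon + max_lon) / 2
    mu = math.log(scenario.trip_distance_median_m)
    dist_floor = 1.2 * radius_m

    # does the system tile its bounding box (e.g. a grid)?  If so a
    # bbox-margin test is enough to accept jittered points cheaply.
    from shapely.ops import unary_union

    bbox_area = (max_lat - min_lat) * (max_lon - min_lon)
    tiles_bbox = abs(unary_union(zones.polygons).area - bbox_area) < 1e-9 * bbox_area

    homes = _sample_places(zones, scenario.n_users, scenario.place_intensity, rng)
    dw = np.asarray(scenario.diurnal_weights, float)
    dw = dw / dw.sum()

    points, truth_trips, truth_days = [], [], []
    for u in range(scenario.n_users):
        uid = f"u{u:05d}"
        for d in range(scenario.n_days):
            day = scenario.start_date + timedelta(days=d)
            mover = rng.random() < scenario.p_mover
            if mover:
                n_trips = 1 + rng.poisson(scenario.trips_per_mover_day - 1.0)
            else:
                n_trips = 0
            visits = [tuple(homes[u])]
            for _ in range(n_trips):
                lat0, lon0 = visits[-1]
                d_m = max(float(rng.lognormal(mu, scenario.trip_distance_sigma)), dist_floor)
                nxt = None
                for _try in range(24):
                    b = rng.uniform(0, 2 * math.pi)
                    cand = _step(lat0, lon0, d_m, b)
                    if zones.locate(np.array([cand[0]]), np.array([cand[1]]))[0] >= 0:
                        nxt = cand
                        break
                if nxt is None:
                    # head toward the system centre; capped so we stay inside
                    to_centre = float(haversine_m(lat0, lon0, clat, clon))
                    d_m = min(d_m, max(dist_floor, 0.8 * to_centre))
                    b = math.atan2(
                        (clon - lon0) * math.cos(math.radians(lat0)), clat - lat0
                    )
                    nxt = _step(lat0, lon0, d_m, b)
                truth_trips.append(
                    (
                        uid,
                        day,
                        visits[-1][0],
                        visits[-1][1],
                        nxt[0],
                        nxt[1],
                        float(haversine_m(visits[-1][0], visits[-1][1], nxt[0], nxt[1])),
                    )
                )
                visits.append(nxt)
            truth_days.append((uid, day, mover, n_trips))

            n_pts = [1 + rng.poisson(scenario.points_per_visit - 1.0) for _ in visits]
            total = sum(n_pts)
            hours = rng.choice(24, size=total, p=dw)
            secs = np.sort(hours * 3600 + rng.integers(0, 3600, total))
            pos = 0
            for (plat, plon), npv in zip(visits, n_pts):
                # fast path: a place this far from the hull can jitter freely
                mlat = scenario.jitter_m / M_PER_DEG_LAT
                mlon = mlat / math.cos(math.radians(plat))
                interior = tiles_bbox and (
                    min_lat + mlat < plat < max_lat - mlat
                    and min_lon + mlon < plon < max_lon - mlon
                )
                for _ in range(npv):
                    jlat, jlon = plat, plon  # the place itself is inside
                    for _try in range(8):
                        ang = rng.uniform(0, 2 * math.pi)
                        rad = scenario.jitter_m * math.sqrt(rng.random())
                        cand = _step(plat, plon, rad, ang)
                        if interior or zones.locate(
                            np.array([cand[0]]), np.array([cand[1]])
                        )[0] >= 0:
                            jlat, jlon = cand
                            break
                    t = datetime(
                        day.year, day.month, day.day, tzinfo=timezone.utc
                    ) + timedelta(seconds=int(secs[pos]))
                    points.append((uid, t, jlat, jlon))
                    pos += 1

    pts = pd.DataFrame(points, columns=["user_id", "timestamp", "lat", "lon"])
    tt = pd.DataFrame(
        truth_trips,
        columns=["user_id", "date", "origin_lat", "origin_lon", "dest_lat", "dest_lon", "distance_m"],
    )
    td = pd.DataFrame(truth_days, columns=["user_id", "date", "is_mover", "n_trips"])
    return pts, tt, td


@dataclass
class CaseScenario:
    """Parameters of the synthetic weekly case-count generator."""

    rho: float = 0.0  # SAR spatial-autocorrelation strength, |rho| < 1
    coupling_b: float = 0.0  # cases per SD of zone attractiveness
    base_rate: float = 20.0  # mean cases per zone-week
    noise_sd: float = 1.0
    poisson: bool = False  # sample counts instead of rounding
    seed: int = 0

    def validate(self) -> None:
        if abs(self.rho) >= 1.0:
            raise ValueError("|rho| must be < 1 for an invertible SAR system")
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")


def generate_cases(
    zones: ZoneSystem,
    weights: SpatialWeights,
    attractiveness: pd.DataFrame,
    scenario: CaseScenario,
) -> pd.DataFrame:
    """Weekly zone-level case counts coupled to attractiveness.

    Per week, a latent field solves the simultaneous-autoregressive
    system ``u = rho * W u + eps`` with ``eps ~ N(0, noise_sd)``;
    expected cases are ``base_rate + coupling_b * standardized
    attractiveness + u``, rounded and floored at zero (or Poisson
    sampled when the scenario asks for it).

    ``attractiveness`` is wide: index = week_start dates, columns =
    zone ids covering the weight matrix's zones.

    Returns long ``zone_id, week_start, cases``.
    """
    scenario.validate()
    ids = weights.ids
    missing = [z for z in ids if z not in attractiveness.columns]
    if missing:
        raise ValueError(f"attractiveness missing zones: {missing[:5]}")
    rng = np.random.default_rng(scenario.seed)
    n = len(ids)
    inv = np.linalg.inv(np.eye(n) - scenario.rho * weights.matrix)
    rows = []
    for wk in attractiveness.index:
        a = attractiveness.loc[wk, ids].to_numpy(dtype=float)
        sd = a.std(ddof=0)
        za = (a - a.mean()) / sd if sd > 0 else np.zeros(n)
        u = inv @ rng.normal(0.0, scenario.noise_sd, n)
        mean = scenario.base_rate + scenario.coupling_b * za + u
        if scenario.poisson:
            counts = rng.poisson(np.clip(mean, 0.0, None))
        else:
            counts = np.maximum(0, np.rint(mean)).astype(int)
        rows.extend((z, wk, int(c)) for z, c in zip(ids, counts))
    return pd.DataFrame(rows, columns=["zone_id", "week_start", "cases"])


def write_points_csv(points: pd.DataFrame, path) -> None:
    out = points.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)
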