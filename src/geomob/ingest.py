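"""Reading, validating and cleaning geo-located point streams.

Cleaning mirrors the rules used for geotagged social-media corpora in
urban-mobility work, applied in order:

1. crop to the study area (point-in-polygon against the zone system;
   boundary points count as inside);
2. drop *abnormal accounts* — users whose yearly post count exceeds the
   yearly mean by ``k`` sample standard deviations (bots, commercial
   feeds); strict inequality, per calendar year of data present;
3. drop *static users* — users whose every post carries one exact
   coordinate pair (they can never produce a trip).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .zones import ZoneSystem

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("user_id", "timestamp", "lat", "lon")


@dataclass
class CleaningReport:
    """Stage-by-stage record of what cleaning removed."""

    n_input: int = 0
    n_invalid_rows_dropped: int = 0
    n_after_read: int = 0
    n_after_bbox: int = 0
    n_users_removed_abnormal: int = 0
    n_after_abnormal: int = 0
    n_static_users_removed: int = 0
    n_after_static: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def read_points(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a point table from CSV or JSON-lines.

    Required columns: ``user_id, timestamp, lat, lon``.  Rows with
    missing/unparseable timestamps or out-of-range coordinates are
    dropped and counted in the log; a missing column is a hard error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if fmt == "csv":
        raw = pd.read_csv(path, dtype={"user_id": str})
    elif fmt == "jsonl":
        raw = pd.read_json(path, lines=True, dtype={"user_id": str})
        if raw.empty:
            raw = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if raw.empty:
        logger.warning("point file %s is empty", path)
        return raw[list(REQUIRED_COLUMNS)]

    n0 = len(raw)
    raw["user_id"] = raw["user_id"].astype(str)
    raw["timestamp"] = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce", format="mixed")
    raw["lat"] = pd.to_numeric(raw["lat"], errors="coerce")
    raw["lon"] = pd.to_numeric(raw["lon"], errors="coerce")
    ok = (
        raw["timestamp"].notna()
        & raw["lat"].between(-90.0, 90.0)
        & raw["lon"].between(-180.0, 180.0)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d invalid rows while reading %s", dropped, path)
    out = raw.loc[ok, list(REQUIRED_COLUMNS)].reset_index(drop=True)
    out.attrs["n_invalid_rows_dropped"] = dropped
    out.attrs["n_input"] = n0
    return out


def filter_bounds(points: pd.DataFrame, zones: ZoneSystem) -> pd.DataFrame:
    """Retain only points falling inside some zone polygon."""
    if points.empty:
        return points.copy()
    idx = zones.locate(points["lat"].to_numpy(), points["lon"].to_numpy())
    return points.loc[idx >= 0].reset_index(drop=True)


def remove_abnormal_accounts(
    points: pd.DataFrame, k: float = 1.0
) -> tuple[pd.DataFrame, dict]:
    """Remove users posting abnormally often (likely bots/commercial).

    Within each calendar year present in the table, a user is removed
    when their post count strictly exceeds ``mean + k * sample SD`` of
    per-user counts for that year.  ``k=inf`` disables the filter.

    Returns the filtered table and a small stats dict.
    """
    if points.empty or math.isinf(k):
        return points.copy(), {"n_users_removed": 0, "k": k}
    pts = points.copy()
    years = pd.to_datetime(pts["timestamp"], utc=True).dt.year
    removed_users: set[tuple[int, str]] = set()
    keep = np.ones(len(pts), dtype=bool)
    for year, grp in pts.groupby(years):
        counts = grp.groupby("user_id").size()
        sd = counts.std(ddof=1)  # sample SD; 0 for a single user
        if np.isnan(sd):
            sd = 0.0
        threshold = counts.mean() + k * sd
        bad = set(counts.index[counts > threshold])
        if bad:
            mask = (years == year) & pts["user_id"].isin(bad)
            keep &= ~mask.to_numpy()
            removed_users.update((year, u) for u in bad)
    report = {"n_users_removed": len(removed_users), "k": k}
    return pts.loc[keep].reset_index(drop=True), report


def remove_static_users(points: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove users whose points all share one exact coordinate pair."""
    if points.empty:
        return points.copy(), {"n_users_removed": 0}
    nun = points.groupby("user_id")[["lat", "lon"]].nunique()
    static = nun.index[(nun["lat"] == 1) & (nun["lon"] == 1)]
    # a user with one unique lat and one unique lon has a single pair
    out = points.loc[~points["user_id"].isin(static)].reset_index(drop=True)
    return out, {"n_users_removed": int(len(static))}


def clean_points(
    points: pd.DataFrame,
    zones: ZoneSystem,
    k_sd: float = 1.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Full cleaning pipeline: bbox -> abnormal accounts -> static users."""
    report = CleaningReport(
        n_input=points.attrs.get("n_input", len(points)),
        n_invalid_rows_dropped=points.attrs.get("n_invalid_rows_dropped", 0),
        n_after_read=len(points),
        thresholds={"k_sd": k_sd},
    )
    pts = filter_bounds(points, zones)
    report.n_after_bbox = len(pts)
    pts, ab = remove_abnormal_accounts(pts, k=k_sd)
    report.n_users_removed_abnormal = ab["n_users_removed"]
    report.n_after_abnormal = len(pts)
    pts, st = remove_static_users(pts)
    report.n_static_users_removed = st["n_users_removed"]
    report.n_after_static = len(pts)
    return pts, report
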