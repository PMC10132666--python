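"""Per-zone weekly attractiveness profiles and their clustering.

Each zone's attractiveness share over the analysis weeks forms a
fixed-length temporal profile (112 weeks in the London study window,
2019-01-07 through 2021-02-22).  Zones are grouped by the *shape* of
their profile — agglomerative clustering under correlation distance
``d = 1 - Pearson r`` — so a zone that doubled its share but followed
the same trend co-clusters with its template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

STUDY_FIRST_WEEK = date(2019, 1, 7)
STUDY_LAST_WEEK = date(2021, 2, 22)


def week_index(start_week_monday: date, end_week_monday: date) -> list[date]:
    """Inclusive list of consecutive Mondays between two Monday dates."""
    start = pd.Timestamp(start_week_monday).date()
    end = pd.Timestamp(end_week_monday).date()
    if start.weekday() != 0 or end.weekday() != 0:
        raise ValueError("week boundaries must be Mondays")
    if start > end:
        raise ValueError("start week is after end week")
    n = (end - start).days // 7 + 1
    return [start + timedelta(weeks=k) for k in range(n)]


def build_profiles(
    weekly_attractiveness: pd.DataFrame, weeks: list[date]
) -> pd.DataFrame:
    """Fixed-length profile per zone from long weekly attractiveness.

    ``weekly_attractiveness`` has columns ``week_start, zone_id, share``.
    Returns a wide frame (zones x weeks); weeks with no observation for
    a zone are 0 — no visits is a real observation, not missing data.
    """
    wa = weekly_attractiveness.copy()
    wa["week_start"] = pd.to_datetime(wa["week_start"]).dt.date
    known = set(weeks)
    stray = set(wa["week_start"]) - known
    if stray:
        raise ValueError(f"weeks outside the index: {sorted(stray)[:3]}...")
    wide = wa.pivot_table(
        index="zone_id", columns="week_start", values="share", fill_value=0.0
    )
    wide = wide.reindex(columns=weeks, fill_value=0.0).sort_index()
    wide.columns.name = "week_start"
    return wide.astype(float)


@dataclass
class ProfileClustering:
    """Result of agglomerative clustering of temporal profiles."""

    labels: pd.Series  # zone_id -> cluster in 0..k-1
    k: int
    linkage_method: str
    merge_table: np.ndarray = field(repr=False)  # scipy linkage matrix
    dropped_zones: list[str] = field(default_factory=list)


def correlation_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ``1 - Pearson r`` between zone profiles (rows)."""
    corr = np.corrcoef(profiles.to_numpy())
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def cluster_profiles(
    profiles: pd.DataFrame, k: int = 3, linkage_method: str = "average"
) -> ProfileClustering:
    """Group zones by temporal-profile shape.

    Zero-variance profiles (constant over all weeks) have no defined
    correlation and are dropped and reported.  Cluster labels are
    renumbered 0..k-1 by the lexicographically smallest member zone id,
    so the labelling is invariant to input row order.
    """
    prof = profiles.sort_index()
    arr = prof.to_numpy()
    sd = arr.std(axis=1)
    # relative threshold: float roundoff on a constant row leaves ~1e-16 scatter
    scale = np.maximum(np.abs(arr).max(axis=1), 1e-300)
    degenerate = sd <= 1e-12 * scale
    dropped = list(prof.index[degenerate])
    prof = prof.loc[~degenerate]
    if len(prof) < k:
        raise ValueError(f"need at least {k} zones with varying profiles, have {len(prof)}")
    dist = correlation_distance_matrix(prof)
    z = linkage(squareform(dist.to_numpy(), checks=False), method=linkage_method)
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber deterministically by smallest zone id in each cluster
    order = sorted(set(raw), key=lambda c: min(prof.index[raw == c]))
    remap = {c: i for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=prof.index, name="cluster")
    return ProfileClustering(
        labels=labels,
        k=k,
        linkage_method=linkage_method,
        merge_table=z,
        dropped_zones=dropped,
    )
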