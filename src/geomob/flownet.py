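"""Weekly origin-destination matrices, flow networks and attractiveness.

Trips are aggregated to Monday-start weeks between zones, giving a
directed, weighted flow network per period.  A zone's *attractiveness*
``A(i,t)`` is its share of all trip arrivals in period ``t`` (weighted
in-degree, self-loops included, divided by the period's total trips),
so the shares sum to one; the *attractiveness difference* between two
periods is the change in share and sums to zero.  Community detection
by modularity maximisation groups zones that exchange more trips with
each other than with the rest of the city; unusually small communities
are flagged as isolated areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .zones import ZoneSystem


def week_start(dates: pd.Series) -> pd.Series:
    """Monday of the ISO week each date falls in."""
    d = pd.to_datetime(dates)
    return (d - pd.to_timedelta(d.dt.weekday, unit="D")).dt.date


def assign_zones(trips: pd.DataFrame, zones: ZoneSystem) -> tuple[pd.DataFrame, int]:
    """Attach origin/destination zone ids to trips by point-in-polygon.

    Trips with an endpoint outside every zone are dropped; the count of
    dropped trips is returned alongside.
    """
    if len(zones) == 0:
        raise ValueError("empty zone system")
    out = trips.copy()
    if out.empty:
        out["origin_zone"] = pd.Series(dtype=object)
        out["dest_zone"] = pd.Series(dtype=object)
        return out, 0
    o = zones.locate_ids(out["origin_lat"].to_numpy(), out["origin_lon"].to_numpy())
    d = zones.locate_ids(out["dest_lat"].to_numpy(), out["dest_lon"].to_numpy())
    out["origin_zone"] = o
    out["dest_zone"] = d
    keep = (out["origin_zone"] != "") & (out["dest_zone"] != "")
    dropped = int((~keep).sum())
    return out.loc[keep].reset_index(drop=True), dropped


def build_weekly_od(trips: pd.DataFrame) -> pd.DataFrame:
    """Aggregate zone-assigned trips to weekly OD counts.

    Weeks are Monday-start and dated by the trip's date.  Intra-zone
    trips are retained as self-loop entries.  Returns a long table with
    columns ``week_start, origin_zone, dest_zone, trips``.
    """
    if trips.empty:
        return pd.DataFrame(columns=["week_start", "origin_zone", "dest_zone", "trips"])
    t = trips.copy()
    t["week_start"] = week_start(t["date"])
    od = (
        t.groupby(["week_start", "origin_zone", "dest_zone"], sort=True)
        .size()
        .rename("trips")
        .reset_index()
    )
    return od


def aggregate_od(od: pd.DataFrame, start, end) -> pd.DataFrame:
    """Sum weekly OD entries whose week_start falls in [start, end]."""
    ws = pd.to_datetime(od["week_start"])
    sel = od.loc[(ws >= pd.Timestamp(start)) & (ws <= pd.Timestamp(end))]
    return (
        sel.groupby(["origin_zone", "dest_zone"], sort=True)["trips"]
        .sum()
        .reset_index()
    )


def od_to_network(od: pd.DataFrame, period: str = "") -> nx.DiGraph:
    """Directed weighted graph from OD entries (one period's rows)."""
    g = nx.DiGraph(period=period)
    for row in od.itertuples(index=False):
        g.add_edge(row.origin_zone, row.dest_zone, weight=int(row.trips))
    return g


def attractiveness(net: nx.DiGraph, direction: str = "in") -> pd.Series:
    """Zone share of period trips: weighted degree / total trip count.

    ``direction`` selects weighted in-degree (default — arrivals, i.e.
    how much a zone is visited), out-degree, or total degree.  Shares
    sum to 1 in "in"/"out" mode on any nonempty network.
    """
    total = sum(w for _, _, w in net.edges(data="weight"))
    if total <= 0:
        raise ValueError("attractiveness undefined on an empty network")
    if direction == "in":
        deg = dict(net.in_degree(weight="weight"))
    elif direction == "out":
        deg = dict(net.out_degree(weight="weight"))
    elif direction == "total":
        deg = dict(net.degree(weight="weight"))
        total *= 2
    else:
        raise ValueError(f"unknown direction {direction!r}")
    s = pd.Series(deg, dtype=float).sort_index() / total
    s.index.name = "zone_id"
    return s


def attractiveness_diff(curr: pd.Series, base: pd.Series) -> pd.Series:
    """Change in attractiveness share between two periods.

    Zones absent from one period count as share 0 there; the
    differences sum to zero because each input sums to one.
    """
    if curr.empty and base.empty:
        raise ValueError("both periods empty")
    idx = curr.index.union(base.index).sort_values()
    d = curr.reindex(idx, fill_value=0.0) - base.reindex(idx, fill_value=0.0)
    d.index.name = "zone_id"
    return d


def network_summary(net: nx.DiGraph) -> dict:
    """Node/edge counts and the intra-zone trip share.

    ``n_edges`` counts distinct directed zone pairs excluding
    self-loops; self-loop trips are reported via
    ``intra_zone_trip_share``.
    """
    loops = [(u, v, w) for u, v, w in net.edges(data="weight") if u == v]
    total = sum(w for _, _, w in net.edges(data="weight"))
    intra = sum(w for _, _, w in loops)
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges() - len(loops),
        "intra_zone_trip_share": intra / total if total else float("nan"),
    }


@dataclass
class CommunityPartition:
    """Zone -> community labels with modularity and isolation flags."""

    period: str
    labels: dict[str, int]
    modularity: float
    sizes: list[int]
    isolated: dict[int, bool]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.period, z, c, self.isolated[c]) for z, c in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["period", "zone_id", "community", "isolated"])


def detect_communities(net: nx.DiGraph, sd_mult: float = 1.0) -> CommunityPartition:
    """Greedy modularity communities on the symmetrized flow graph.

    Edge weights are summed over the two directions (self-loops kept)
    and communities found by deterministic greedy modularity
    maximisation.  Communities whose size falls strictly below
    ``max(1, mean size - sd_mult * SD of sizes)`` are flagged isolated:
    they are the scattered, weakly connected pockets of the city.
    """
    if net.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    und = nx.Graph()
    for u, v, w in net.edges(data="weight"):
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    comms = nx.community.greedy_modularity_communities(und, weight="weight")
    # deterministic label order: communities sorted by (size desc, min zone id)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    q = nx.community.modularity(und, [set(c) for c in comms], weight="weight")
    labels = {z: i for i, c in enumerate(comms) for z in c}
    sizes = [len(c) for c in comms]
    mean = float(np.mean(sizes))
    sd = float(np.std(sizes, ddof=0))
    threshold = max(1.0, mean - sd_mult * sd)
    isolated = {i: (len(c) < threshold) for i, c in enumerate(comms)}
    return CommunityPartition(
        period=str(net.graph.get("period", "")),
        labels=labels,
        modularity=float(q),
        sizes=sizes,
        isolated=isolated,
    )
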