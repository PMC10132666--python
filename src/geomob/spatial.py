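"""Spatial weights and Moran-family autocorrelation statistics.

First-order queen contiguity (zones sharing any boundary point are
neighbours) with row-standardized weights, and permutation-based
inference for:

* global Moran's I — is a zone attribute spatially clustered?
* local Moran's I (LISA) — which zones sit in high-high / low-low
  clusters or are spatial outliers?
* bivariate Moran's I, global and local — is one attribute (e.g. zone
  attractiveness) surrounded by high values of another (e.g. reported
  case counts)?

All statistics use z-standardized inputs (population SD) and the
row-standardized weight matrix.  Inference is by random relabelling:
the two-sided pseudo p-value is ``(#permutations at least as extreme
+ 1) / (n_perm + 1)``, extremity measured as distance from the null
expectation.  The bivariate null holds x fixed and permutes y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zones import ZoneSystem

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 999


@dataclass
class SpatialWeights:
    """Row-standardized first-order contiguity weights."""

    ids: list[str]
    neighbors: dict[str, list[str]]
    matrix: np.ndarray = field(repr=False)  # row-standardized, zero diagonal

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        """Sum of all weights (= number of non-island zones here)."""
        return float(self.matrix.sum())

    @property
    def islands(self) -> list[str]:
        return [z for z in self.ids if not self.neighbors[z]]

    def subset(self, keep_ids: list[str]) -> "SpatialWeights":
        """Weights restricted to a zone subset, re-standardized."""
        pos = {z: i for i, z in enumerate(self.ids)}
        idx = [pos[z] for z in keep_ids]
        raw = (self.matrix[np.ix_(idx, idx)] > 0).astype(float)
        return _standardize(keep_ids, raw)


def _standardize(ids: list[str], adjacency: np.ndarray) -> SpatialWeights:
    rowsums = adjacency.sum(axis=1, keepdims=True)
    w = np.divide(adjacency, rowsums, out=np.zeros_like(adjacency), where=rowsums > 0)
    neighbors = {
        ids[i]: [ids[j] for j in np.flatnonzero(adjacency[i])] for i in range(len(ids))
    }
    return SpatialWeights(ids=list(ids), neighbors=neighbors, matrix=w)


def queen_weights(zones: ZoneSystem) -> SpatialWeights:
    """First-order queen contiguity from zone polygons.

    Zones sharing at least one boundary point (edge or corner) are
    neighbours.  Zones with no neighbour (islands) get an all-zero row
    and are logged; downstream Moran statistics reject all-island
    systems.
    """
    n = len(zones)
    adj = np.zeros((n, n))
    left, right = zones._tree.query(list(zones.polygons), predicate="intersects")
    for i, j in zip(left, right):
        if i != j:
            adj[i, j] = 1.0
    adj = np.maximum(adj, adj.T)
    w = _standardize(list(zones.zone_ids), adj)
    if w.islands:
        logger.info("queen weights: %d island zones %s", len(w.islands), w.islands[:5])
    return w


@dataclass
class MoranResult:
    """A Moran statistic with its permutation-null summary."""

    statistic: float
    expected: float
    p_value: float
    n_permutations: int
    seed: int | None
    permuted: np.ndarray = field(repr=False, default=None)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("Moran statistics are undefined for a constant attribute")
    return (x - x.mean()) / sd


def _pseudo_p(obs: float, perms: np.ndarray, center: float) -> float:
    extreme = np.abs(perms - center) >= abs(obs - center) - 1e-15
    return (int(extreme.sum()) + 1) / (len(perms) + 1)


def morans_i(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with random-relabelling inference.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    """
    x = np.asarray(x, dtype=float)
    if x.size != w.n:
        raise ValueError("attribute length must match the weights")
    if x.size < 2:
        raise ValueError("need at least 2 zones")
    if w.s0 == 0:
        raise ValueError("weights have no links (all islands)")
    z = x - x.mean()
    if (z == 0).all():
        raise ValueError("Moran's I is undefined for a constant attribute")
    denom = float(z @ z)
    scale = x.size / w.s0
    obs = scale * float(z @ (w.matrix @ z)) / denom
    expected = -1.0 / (x.size - 1)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        zp = rng.permutation(z)
        perms[k] = scale * float(zp @ (w.matrix @ zp)) / denom
    return MoranResult(
        statistic=obs,
        expected=expected,
        p_value=_pseudo_p(obs, perms, expected),
        n_permutations=n_perm,
        seed=seed,
        permuted=perms,
    )


def _quadrant(zi: float, lag: float) -> str:
    if zi == 0 or lag == 0:
        return ""
    if zi > 0:
        return "HH" if lag > 0 else "HL"
    return "LH" if lag > 0 else "LL"


def local_morans(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Local Moran's I (LISA) with conditional permutation inference.

    I_i = z_i * sum_j w_ij z_j on z-standardized x.  For each zone the
    null redraws its neighbours' values from the other zones without
    replacement, holding z_i fixed.  Quadrants: HH/LL are spatial
    clusters, HL/LH spatial outliers; blank where either deviation is
    exactly zero.
    """
    x = np.asarray(x, dtype=float)
    z = _zscore(x)
    lag = w.matrix @ z
    obs = z * lag
    rng = np.random.default_rng(seed)
    n = x.size
    pvals = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        ki = int((w.matrix[i] > 0).sum())
        if ki == 0:
            pvals[i] = np.nan
            continue
        draws = np.empty(n_perm)
        for k in range(n_perm):
            sample = others[rng.choice(n - 1, size=ki, replace=False)]
            draws[k] = z[i] * sample.mean()  # row-standardized lag
        pvals[i] = _pseudo_p(obs[i], draws, 0.0)
    quad = [_quadrant(z[i], lag[i]) for i in range(n)]
    return pd.DataFrame(
        {
            "zone_id": w.ids,
            "local_i": obs,
            "quadrant": quad,
            "p_value": pvals,
            "significant": pvals <= alpha,
        }
    )


def bivariate_morans_i(
    x: np.ndarray,
    y: np.ndarray,
    w: SpatialWeights,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MoranResult:
    """Global bivariate Moran's I: is x surrounded by high y?

    I_xy = (n / S0) * sum_ij w_ij zx_i zy_j / sum_i zx_i^2 with both
    variables z-standardized.  The permutation null holds x fixed and
    relabels y; the null expectation is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != w.n or y.size != w.n:
        raise ValueError("attribute lengths must match the weights")
    zx, zy = _zscore(x), _zscore(y)
    scale = x.size / w.s0
    denom = float(zx @ zx)
    obs = scale * float(zx @ (w.matrix @ zy)) / denom
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        zp = rng.permutation(zy)
        perms[k] = scale * float(zx @ (w.matrix @ zp)) / denom
    return MoranResult(
        statistic=obs,
        expected=0.0,
        p_value=_pseudo_p(obs, perms, 0.0),
        n_permutations=n_perm,
        seed=seed,
        permuted=perms,
    )


def local_bivariate_morans(
    x: np.ndarray,
    y: np.ndarray,
    w: SpatialWeights,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Local bivariate Moran: I_i = zx_i * (W zy)_i, y permuted null."""
    zx, zy = _zscore(np.asarray(x, float)), _zscore(np.asarray(y, float))
    lag = w.matrix @ zy
    obs = zx * lag
    rng = np.random.default_rng(seed)
    n = zx.size
    pvals = np.empty(n)
    for i in range(n):
        others = np.delete(zy, i)
        ki = int((w.matrix[i] > 0).sum())
        if ki == 0:
            pvals[i] = np.nan
            continue
        draws = np.empty(n_perm)
        for k in range(n_perm):
            sample = others[rng.choice(n - 1, size=ki, replace=False)]
            draws[k] = zx[i] * sample.mean()
        pvals[i] = _pseudo_p(obs[i], draws, 0.0)
    quad = [_quadrant(zx[i], lag[i]) for i in range(n)]
    return pd.DataFrame(
        {
            "zone_id": w.ids,
            "local_i": obs,
            "quadrant": quad,
            "p_value": pvals,
            "significant": pvals <= alpha,
        }
    )


def correlation_row(
    attr: pd.Series,
    cases: pd.Series,
    w: SpatialWeights,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """The four correlation measures for one period on aligned zones.

    Zones missing from ``attr`` are treated as share 0 (no visits);
    zones missing from ``cases`` are dropped (with the weights
    re-standardized on the remainder) and counted.  Degenerate inputs
    (constant attribute over zones) yield NaN statistics, not errors.
    """
    from scipy.stats import pearsonr

    keep = [z for z in w.ids if z in cases.index]
    dropped = w.n - len(keep)
    if dropped:
        logger.info("correlation_row: dropped %d zones missing case data", dropped)
    wsub = w.subset(keep) if dropped else w
    x = attr.reindex(keep).fillna(0.0).to_numpy()
    y = cases.reindex(keep).astype(float).to_numpy()
    out = {
        "pearson_r": np.nan,
        "moran_cases": np.nan,
        "bivar_moran": np.nan,
        "n_sig_local_bivar": np.nan,
        "n_zones": len(keep),
    }
    if x.std() > 0 and y.std() > 0:
        out["pearson_r"] = float(pearsonr(x, y)[0])
    if y.std() > 0:
        out["moran_cases"] = morans_i(y, wsub, n_perm=n_perm, seed=seed).statistic
    if x.std() > 0 and y.std() > 0:
        out["bivar_moran"] = bivariate_morans_i(x, y, wsub, n_perm=n_perm, seed=seed).statistic
        loc = local_bivariate_morans(x, y, wsub, n_perm=n_perm, seed=seed, alpha=alpha)
        out["n_sig_local_bivar"] = int(loc["significant"].sum())
    return out


def weekly_correlation_suite(
    weekly_attr: pd.DataFrame,
    cases: pd.DataFrame,
    w: SpatialWeights,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Weekly Pearson / Moran / bivariate-Moran series.

    ``weekly_attr``: long ``week_start, zone_id, share``;
    ``cases``: long ``zone_id, week_start, cases``.  One row per week
    present in both sources.
    """
    wa = weekly_attr.copy()
    wa["week_start"] = pd.to_datetime(wa["week_start"]).dt.date
    cs = cases.copy()
    cs["week_start"] = pd.to_datetime(cs["week_start"]).dt.date
    weeks = sorted(set(wa["week_start"]) & set(cs["week_start"]))
    if not weeks:
        raise ValueError("no overlapping weeks between attractiveness and cases")
    ss = np.random.SeedSequence(seed)
    rows = []
    for wk, child in zip(weeks, ss.spawn(len(weeks))):
        attr = wa.loc[wa["week_start"] == wk].set_index("zone_id")["share"]
        case = cs.loc[cs["week_start"] == wk].set_index("zone_id")["cases"]
        wk_seed = int(child.generate_state(1)[0] % (2**31))
        row = correlation_row(attr, case, w, n_perm=n_perm, seed=wk_seed, alpha=alpha)
        row["week_start"] = wk
        rows.append(row)
    return pd.DataFrame(rows)[
        ["week_start", "pearson_r", "moran_cases", "bivar_moran", "n_sig_local_bivar", "n_zones"]
    ]
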