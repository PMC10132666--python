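"""Zone systems: polygon partitions of a study area.

A :class:`ZoneSystem` is an ordered collection of named, valid,
interior-disjoint polygons in WGS84 (lon/lat degrees).  It stands in for
census reporting geographies such as the UK's Middle Layer Super Output
Areas (MSOAs): the statistics downstream depend only on the contiguity
topology and on which zone each point falls in, not on the exact shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import STRtree
from shapely.geometry import Polygon, mapping, shape


@dataclass(frozen=True)
class ZoneSystem:
    """An ordered set of uniquely-named WGS84 polygons.

    Parameters
    ----------
    zone_ids
        Unique identifier per zone, aligned with ``polygons``.
    polygons
        Valid shapely polygons with pairwise disjoint interiors.
    """

    zone_ids: tuple[str, ...]
    polygons: tuple[Polygon, ...]
    _tree: STRtree = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.zone_ids) != len(self.polygons):
            raise ValueError("zone_ids and polygons must align")
        if len(set(self.zone_ids)) != len(self.zone_ids):
            raise ValueError("zone ids must be unique")
        for zid, poly in zip(self.zone_ids, self.polygons):
            if not poly.is_valid:
                raise ValueError(f"invalid polygon for zone {zid!r}")
        object.__setattr__(self, "_tree", STRtree(list(self.polygons)))

    def __len__(self) -> int:
        return len(self.zone_ids)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the whole system."""
        b = np.array([p.bounds for p in self.polygons])
        return (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())

    def index_of(self, zone_id: str) -> int:
        return self.zone_ids.index(zone_id)

    def locate(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Zone index for each point, -1 if outside every zone.

        Boundary points count as inside; a point on a shared edge is
        assigned to the zone with the smallest index (deterministic).
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        from shapely import points as mk_points

        pts = mk_points(lon, lat)
        out = np.full(len(pts), -1, dtype=int)
        pt_idx, poly_idx = self._tree.query(pts, predicate="intersects")
        # keep the smallest polygon index per point for tie determinism
        order = np.lexsort((poly_idx, pt_idx))
        pt_idx, poly_idx = pt_idx[order], poly_idx[order]
        first = np.unique(pt_idx, return_index=True)[1]
        out[pt_idx[first]] = poly_idx[first]
        return out

    def locate_ids(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Zone id per point, empty string if outside."""
        idx = self.locate(lat, lon)
        ids = np.array(self.zone_ids + ("",), dtype=object)
        return ids[idx]

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"zone_id": zid},
                "geometry": mapping(poly),
            }
            for zid, poly in zip(self.zone_ids, self.polygons)
        ]
        doc = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ZoneSystem":
        doc = json.loads(Path(path).read_text())
        ids, polys = [], []
        for feat in doc["features"]:
            ids.append(str(feat["properties"]["zone_id"]))
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise ValueError("zone features must be Polygons")
            polys.append(geom)
        return cls(tuple(ids), tuple(polys))


def generate_zones(
    rows: int,
    cols: int,
    cell_deg: float,
    origin: tuple[float, float] = (51.35, -0.35),
) -> ZoneSystem:
    """Tile a rectangle with ``rows`` x ``cols`` square grid zones.

    ``origin`` is the (lat, lon) of the south-west corner.  Zone ids are
    deterministic ``Z_<row>_<col>`` with row 0 at the southern edge.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if cell_deg <= 0:
        raise ValueError("cell_deg must be positive")
    lat0, lon0 = origin
    # shared lattice coordinates so adjacent cells touch exactly
    lats = lat0 + np.arange(rows + 1) * cell_deg
    lons = lon0 + np.arange(cols + 1) * cell_deg
    ids, polys = [], []
    for r in range(rows):
        for c in range(cols):
            polys.append(
                Polygon(
                    [
                        (lons[c], lats[r]),
                        (lons[c + 1], lats[r]),
                        (lons[c + 1], lats[r + 1]),
                        (lons[c], lats[r + 1]),
                        (lons[c], lats[r]),
                    ]
                )
            )
            ids.append(f"Z_{r}_{c}")
    return ZoneSystem(tuple(ids), tuple(polys))
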