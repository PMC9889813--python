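"""Municipality geometry: centroid distances and spatial neighborhood structures.

Two adjacency constructions are supported, mirroring common practice in
small-area disease mapping:

* queen contiguity — two municipalities are neighbors when their polygon
  boundaries share at least one point (edge or corner);
* k-nearest neighbors (default k = 8) on centroid distances, symmetrized
  by union so the neighbor relation is always symmetric.

Distances are great-circle (haversine, sphere radius 6371 km) for
latitude/longitude input, or planar Euclidean when coordinates are
already in kilometres (synthetic layouts), selected by ``metric``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class MunicipalityGeo:
    """Centroid coordinates (lat/lon degrees or planar km) and optional polygon."""

    municipality_id: str
    lat: float
    lon: float
    polygon: BaseGeometry | None = None


@dataclass
class AdjacencyStructure:
    """Symmetric neighbor sets without self-loops."""

    neighbor_sets: dict[str, frozenset[str]]
    kind: str  # "queen" | "knn"

    def neighbors(self, unit_id: str) -> frozenset[str]:
        return self.neighbor_sets[unit_id]

    def is_symmetric(self) -> bool:
        return all(
            i in self.neighbor_sets[j]
            for i, nbrs in self.neighbor_sets.items()
            for j in nbrs
        )

    def to_edge_list(self) -> pd.DataFrame:
        edges = sorted(
            (i, j)
            for i, nbrs in self.neighbor_sets.items()
            for j in nbrs
            if i < j
        )
        return pd.DataFrame(edges, columns=["id_a", "id_b"])


def _validate_latlon(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
        raise ValueError("coordinates outside lat [-90,90] / lon [-180,180]")


def haversine_km(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat = np.array([p[0], q[0]], dtype=float)
    lon = np.array([p[1], q[1]], dtype=float)
    _validate_latlon(lat, lon)
    phi1, phi2 = np.radians(lat)
    dphi = phi2 - phi1
    dlmb = np.radians(lon[1] - lon[0])
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def distance_matrix(
    lat: Sequence[float], lon: Sequence[float], metric: str = "haversine"
) -> np.ndarray:
    """All-pairs distance matrix in km; ``metric`` is haversine or planar."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if metric == "planar":
        dx = lat[:, None] - lat[None, :]
        dy = lon[:, None] - lon[None, :]
        return np.hypot(dx, dy)
    if metric != "haversine":
        raise ValueError(f"unknown metric: {metric!r}")
    _validate_latlon(lat, lon)
    phi = np.radians(lat)
    lmb = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlmb = lmb[:, None] - lmb[None, :]
    a = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlmb / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def knn_adjacency(
    geos: Sequence[MunicipalityGeo], k: int = 8, metric: str = "haversine"
) -> AdjacencyStructure:
    """k-nearest-neighbor adjacency on centroids, symmetrized by union.

    Ties in distance are broken by ascending municipality id, making the
    construction deterministic and invariant to input order.
    """
    n = len(geos)
    if k <= 0 or k >= n:
        raise ValueError(f"k must be in [1, n-1]; got k={k}, n={n}")
    ids = [g.municipality_id for g in geos]
    if len(set(ids)) != n:
        raise ValueError("duplicate municipality ids")
    order = np.argsort(np.array(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    lat = np.array([geos[i].lat for i in order])
    lon = np.array([geos[i].lon for i in order])
    d = distance_matrix(lat, lon, metric=metric)

    nbrs: dict[str, set[str]] = {i: set() for i in ids_sorted}
    for i in range(n):
        # stable sort over (distance, id-rank); ids already in ascending order
        cand = np.argsort(d[i], kind="stable")
        cand = cand[cand != i][:k]
        for j in cand:
            nbrs[ids_sorted[i]].add(ids_sorted[j])
            nbrs[ids_sorted[j]].add(ids_sorted[i])  # union symmetrization
    return AdjacencyStructure(
        neighbor_sets={i: frozenset(s) for i, s in nbrs.items()}, kind="knn"
    )


def queen_adjacency(geos: Sequence[MunicipalityGeo]) -> AdjacencyStructure:
    """Queen contiguity: adjacent iff boundaries share at least one point."""
    missing = [g.municipality_id for g in geos if g.polygon is None]
    if missing:
        raise ValueError(f"municipalities lack polygons: {missing[:10]}")
    ids = [g.municipality_id for g in geos]
    polys = [g.polygon for g in geos]
    tree = STRtree(polys)
    nbrs: dict[str, set[str]] = {i: set() for i in ids}
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            if int(j) != i:
                nbrs[ids[i]].add(ids[int(j)])
    islands = [i for i, s in nbrs.items() if not s]
    if islands:
        log.warning("isolated units (no queen neighbors): %s", islands[:10])
    return AdjacencyStructure(
        neighbor_sets={i: frozenset(s) for i, s in nbrs.items()}, kind="queen"
    )


def read_centroids_csv(path) -> list[MunicipalityGeo]:
    """Read geometry CSV ``municipality_id,lat,lon``."""
    df = pd.read_csv(path, dtype={"municipality_id": str})
    return [
        MunicipalityGeo(str(r.municipality_id), float(r.lat), float(r.lon))
        for r in df.itertuples()
    ]


def read_geojson(path) -> list[MunicipalityGeo]:
    """Read a GeoJSON FeatureCollection with a ``municipality_id`` property."""
    with open(path) as fh:
        fc = json.load(fh)
    geos = []
    for feat in fc["features"]:
        poly = shape(feat["geometry"])
        c = poly.centroid
        geos.append(
            MunicipalityGeo(
                municipality_id=str(feat["properties"]["municipality_id"]),
                lat=c.y,
                lon=c.x,
                polygon=poly,
            )
        )
    return geos


def write_geojson(geos: Sequence[MunicipalityGeo], properties: pd.DataFrame, path):
    """Write polygons (or point centroids) with per-unit properties for mapping."""
    props = properties.set_index("municipality_id")
    features = []
    for g in geos:
        geom = g.polygon if g.polygon is not None else None
        geometry = (
            json.loads(json.dumps(geom.__geo_interface__))
            if geom is not None
            else {"type": "Point", "coordinates": [g.lon, g.lat]}
        )
        row = props.loc[g.municipality_id].to_dict() if g.municipality_id in props.index else {}
        row = {k: (v.item() if hasattr(v, "item") else v) for k, v in row.items()}
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {"municipality_id": g.municipality_id, **row},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
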