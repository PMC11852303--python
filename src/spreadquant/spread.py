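"""Spread quantification: neighbor-graph clustering, minimum convex
polygons, occupied area, and spread rate.

The spread statistic is built per species from point occurrences:

1. Points are grouped by single-linkage connectivity — two points are
   neighbors if their great-circle distance is at most ``link_km``
   (default 50 km). Connected components with fewer than ``min_size``
   points (default 3) are discarded; equivalently, any point farther than
   50 km from its closest neighbor cannot belong to a cluster.
2. Each cluster's minimum convex polygon (convex hull) is built and its
   area measured in an equal-area projection.
3. Occupied area is the sum of cluster polygon areas, and the spread rate
   is that area divided by the number of years since the species' first
   collection record, in km²/yr.

Collinear three-point clusters yield a zero-width hull: they are kept in
the output with area 0 and flagged degenerate rather than dropped, so
cluster counts stay faithful to the clustering rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import LineString, MultiPoint, Point, Polygon

from .occurrences import OccurrenceSet
from .projection import EARTH_RADIUS_KM, AlbersEqualArea

__all__ = [
    "Cluster",
    "RangePolygon",
    "SpreadResult",
    "great_circle_km",
    "pairwise_great_circle_km",
    "cluster_points",
    "minimum_convex_polygon",
    "polygon_area_km2",
    "occupied_area",
    "spread_rate",
]

DEFAULT_LINK_KM = 50.0
DEFAULT_MIN_SIZE = 3


def great_circle_km(p, q) -> float:
    """Haversine great-circle distance between two (lon, lat) points, km."""
    lon1, lat1 = np.radians(np.asarray(p, dtype=float))
    lon2, lat2 = np.radians(np.asarray(q, dtype=float))
    a = (
        np.sin(0.5 * (lat2 - lat1)) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin(0.5 * (lon2 - lon1)) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def pairwise_great_circle_km(points: np.ndarray) -> np.ndarray:
    """Full symmetric haversine distance matrix for an (n, 2) lon/lat array."""
    pts = np.asarray(points, dtype=float)
    lon = np.radians(pts[:, 0])[:, None]
    lat = np.radians(pts[:, 1])[:, None]
    a = (
        np.sin(0.5 * (lat.T - lat)) ** 2
        + np.cos(lat) * np.cos(lat.T) * np.sin(0.5 * (lon.T - lon)) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class Cluster:
    """Indices (into the point list) of one single-linkage component."""

    members: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RangePolygon:
    """Minimum convex polygon of a cluster, vertices in lon/lat (WGS84)."""

    vertices: tuple[tuple[float, float], ...]
    area_km2: float
    degenerate: bool = False

    @property
    def shapely(self) -> Polygon | LineString | Point:
        if len(self.vertices) >= 3:
            return Polygon(self.vertices)
        if len(self.vertices) == 2:
            return LineString(self.vertices)
        return Point(self.vertices[0])


@dataclass
class SpreadResult:
    """Per-species spread summary."""

    species_id: str
    clusters: list[Cluster] = field(default_factory=list)
    polygons: list[RangePolygon] = field(default_factory=list)
    occupied_area_km2: float = 0.0
    n_points: int = 0
    years_since_first_record: int | None = None
    spread_rate_km2_per_yr: float | None = None


def cluster_points(
    points,
    link_km: float = DEFAULT_LINK_KM,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[Cluster]:
    """Single-linkage clusters of lon/lat points under a distance threshold.

    Clusters are the connected components of the graph with an edge between
    any two points at great-circle distance ≤ ``link_km``, keeping only
    components of at least ``min_size`` points. The result is independent
    of input order; clusters are returned sorted by smallest member index
    with members ascending.
    """
    if link_km <= 0:
        raise ValueError("link_km must be positive")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    dist = pairwise_great_circle_km(pts)
    adj = csr_matrix(dist <= link_km)
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if len(members) >= min_size:
            clusters.append(Cluster(tuple(int(i) for i in members)))
    clusters.sort(key=lambda cl: cl.members[0])
    return clusters


def minimum_convex_polygon(points, projection=None) -> RangePolygon:
    """Minimum convex polygon (convex hull) of ≥ 3 lon/lat points.

    Collinear input degenerates to a zero-area polygon, flagged.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points for a minimum convex polygon, got {len(pts)}")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type == "Polygon":
        verts = tuple(tuple(v) for v in hull.exterior.coords[:-1])
        degenerate = False
    else:  # LineString or Point: all points collinear/coincident
        verts = tuple(tuple(v) for v in hull.coords)
        degenerate = True
    poly = RangePolygon(vertices=verts, area_km2=0.0, degenerate=degenerate)
    area = 0.0 if degenerate else polygon_area_km2(poly, projection=projection)
    return RangePolygon(vertices=verts, area_km2=area, degenerate=degenerate)


def polygon_area_km2(polygon: RangePolygon, projection=None) -> float:
    """Area of a range polygon in km² under an equal-area projection.

    The default projection is an Albers equal-area conic parameterized
    from the polygon's own vertex extent.
    """
    if polygon.degenerate or len(polygon.vertices) < 3:
        return 0.0
    verts = np.asarray(polygon.vertices, dtype=float)
    if projection is None:
        projection = AlbersEqualArea.from_points(verts[:, 0], verts[:, 1])
    x, y = projection(verts[:, 0], verts[:, 1])
    planar = Polygon(zip(x, y))
    assert planar.is_valid, "convex hull projected to an invalid ring"
    return float(planar.area)


def occupied_area(
    occ: OccurrenceSet,
    species_id: str,
    link_km: float = DEFAULT_LINK_KM,
    min_size: int = DEFAULT_MIN_SIZE,
) -> SpreadResult:
    """Total occupied area (sum of cluster hull areas) for one species.

    A species with no cluster of ``min_size`` points occupies area 0. A
    shared projection, parameterized from all of the species' points, is
    used for every cluster so areas are additive in one plane.
    """
    frame = occ.for_species(species_id)
    if frame.empty:
        raise KeyError(f"unknown species: {species_id!r}")
    pts = frame[["lon", "lat"]].to_numpy(dtype=float)
    result = SpreadResult(species_id=species_id, n_points=len(pts))
    result.clusters = cluster_points(pts, link_km=link_km, min_size=min_size)
    if not result.clusters:
        return result
    projection = AlbersEqualArea.from_points(pts[:, 0], pts[:, 1])
    for cl in result.clusters:
        poly = minimum_convex_polygon(pts[list(cl.members)], projection=projection)
        result.polygons.append(poly)
    result.occupied_area_km2 = float(sum(p.area_km2 for p in result.polygons))
    return result


def spread_rate(area_km2: float, years: int) -> float:
    """Area colonized per year since first record: ``area_km2 / years``."""
    if years < 1:
        raise ValueError(f"years since first record must be >= 1, got {years}")
    return float(area_km2) / float(years)
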