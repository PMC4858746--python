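"""Species range polygons from occurrence records.

The construction rule is dispatched on record count: five or more records
get an alpha hull grown until it is contiguous and contains at least 99%
of the records; 3-4 records get a minimum convex hull; 1-2 records get
0.5-degree point buffers. Ranges are then clipped to the coastline. All
geometry is planar in lon/lat degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "RangePolygon",
    "AlphaHullParams",
    "AlphaHullError",
    "jitter_within_polygon",
    "alpha_shape",
    "grow_alpha_hull",
    "build_range",
    "clip_to_land",
]

BUFFER_RADIUS_DEG = 0.5  # point-buffer radius for 1-2 record species


@dataclass
class OccurrenceSet:
    """Occurrence records for one species (lon/lat degrees)."""

    species: str
    points: np.ndarray  # (n, 2) lon, lat
    georeferenced: "np.ndarray | None" = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        lon, lat = self.points[:, 0], self.points[:, 1]
        if np.any((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside lon/lat bounds")
        if self.georeferenced is None:
            self.georeferenced = np.ones(len(self.points), dtype=bool)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RangePolygon:
    species: str
    geometry: "Polygon"
    method: str  # alpha | hull | buffer | provided

    def __post_init__(self):
        if self.method not in {"alpha", "hull", "buffer", "provided"}:
            raise ValueError(f"unknown range method {self.method!r}")
        if not self.geometry.is_valid:
            self.geometry = make_valid(self.geometry)


@dataclass
class AlphaHullParams:
    """Growth schedule for the alpha-hull construction.

    ``alpha_start`` defaults to the mean nearest-neighbor distance of the
    points (computed per species when None); each iteration multiplies
    alpha by ``growth_factor`` until the shape is one connected polygon
    containing at least ``containment_fraction`` of the records.
    """

    alpha_start: "float | None" = None
    growth_factor: float = 1.5
    max_iterations: int = 50
    containment_fraction: float = 0.99

    def __post_init__(self):
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must exceed 1")
        if not 0 < self.containment_fraction <= 1:
            raise ValueError("containment_fraction must be in (0, 1]")


class AlphaHullError(RuntimeError):
    def __init__(self, msg, last_geometry=None):
        super().__init__(msg)
        self.last_geometry = last_geometry


def jitter_within_polygon(polygon: Polygon, seed: int) -> tuple:
    """Uniform random point inside a polygon (rejection sampling).

    Used to place non-georeferenced records within their municipality's
    political boundary. Deterministic per seed.
    """
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("degenerate polygon")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = polygon.bounds
    for _ in range(100000):
        x = minx + rng.random() * (maxx - minx)
        y = miny + rng.random() * (maxy - miny)
        if polygon.covers(Point(x, y)):
            return (float(x), float(y))
    raise RuntimeError("rejection sampling failed; polygon nearly degenerate")


def _circumradius(pa, pb, pc) -> float:
    a = math.dist(pb, pc)
    b = math.dist(pa, pc)
    c = math.dist(pa, pb)
    s = (a + b + c) / 2.0
    area2 = max(s * (s - a) * (s - b) * (s - c), 0.0)
    if area2 == 0.0:
        return math.inf
    return a * b * c / (4.0 * math.sqrt(area2))


def alpha_shape(points: np.ndarray, alpha: float):
    """Alpha shape: union of Delaunay triangles with circumradius <= alpha.

    With this (radius) convention the shape grows toward the convex hull
    as alpha increases, so it is always a subset of the convex hull.
    """
    points = np.asarray(points, dtype=float)
    try:
        tri = Delaunay(points)
    except Exception as exc:
        raise AlphaHullError(f"degenerate point configuration: {exc}") from exc
    keep = []
    for simplex in tri.simplices:
        pa, pb, pc = points[simplex]
        if _circumradius(tuple(pa), tuple(pb), tuple(pc)) <= alpha:
            keep.append(Polygon([pa, pb, pc]))
    return unary_union(keep)


def _mean_nn_distance(points: np.ndarray) -> float:
    d, _ = cKDTree(points).query(points, k=2)
    return float(np.mean(d[:, 1]))


def grow_alpha_hull(points: np.ndarray, params: "AlphaHullParams | None" = None):
    """Increase alpha until the shape is contiguous and contains >=99% of points.

    Returns ``(polygon, alpha_used)`` for the smallest tested alpha giving
    a single connected polygon covering at least
    ``ceil(containment_fraction * n)`` records (boundary points count as
    contained). Raises :class:`AlphaHullError` (with the last geometry
    attached) when the iteration cap is hit, or a degenerate-geometry
    error on collinear input.
    """
    params = params or AlphaHullParams()
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 5:
        raise ValueError("alpha hull requires at least 5 points")
    need = math.ceil(params.containment_fraction * n)
    alpha = params.alpha_start
    if alpha is None:
        alpha = _mean_nn_distance(points)
    if alpha <= 0:
        alpha = 1e-6
    geom = None
    pts = [Point(p) for p in points]
    for _ in range(params.max_iterations):
        geom = alpha_shape(points, alpha)
        if geom.geom_type == "Polygon" and not geom.is_empty:
            contained = sum(geom.covers(p) for p in pts)
            if contained >= need:
                return geom, alpha
        alpha *= params.growth_factor
    raise AlphaHullError(
        f"no contiguous {params.containment_fraction:.0%}-containing shape "
        f"within {params.max_iterations} iterations",
        last_geometry=geom,
    )


def build_range(
    occ: OccurrenceSet,
    alpha_params: "AlphaHullParams | None" = None,
    buffer_radius: float = BUFFER_RADIUS_DEG,
) -> "RangePolygon | None":
    """Dispatch range construction on record count.

    >=5 records: alpha hull (convex-hull fallback on alpha failure, logged);
    3-4 records: minimum convex hull; 1-2 records: union of
    ``buffer_radius``-degree disks. Zero records: skipped with a warning
    (returns None).
    """
    n = len(occ)
    if n == 0:
        logger.warning("species %s has no records; skipped", occ.species)
        return None
    if n >= 5:
        try:
            geom, _ = grow_alpha_hull(occ.points, alpha_params)
            return RangePolygon(occ.species, geom, "alpha")
        except (AlphaHullError, ValueError) as exc:
            logger.warning(
                "alpha hull failed for %s (%s); falling back to convex hull",
                occ.species, exc,
            )
            return RangePolygon(
                occ.species, MultiPoint(occ.points.tolist()).convex_hull.buffer(0.0),
                "hull",
            )
    if n >= 3:
        hull = MultiPoint(occ.points.tolist()).convex_hull
        if hull.geom_type != "Polygon":  # collinear points: thin buffer
            hull = hull.buffer(buffer_radius)
        return RangePolygon(occ.species, hull, "hull")
    disks = [Point(p).buffer(buffer_radius, quad_segs=64) for p in occ.points]
    return RangePolygon(occ.species, unary_union(disks), "buffer")


def clip_to_land(rng: RangePolygon, coast: Polygon) -> RangePolygon:
    """Intersect a range with the land polygon; may come back empty."""
    if not coast.is_valid:
        coast = make_valid(coast)
    geom = rng.geometry.intersection(coast)
    if not geom.is_valid:
        geom = make_valid(geom)
    if geom.is_empty:
        logger.warning("range of %s entirely at sea after clipping", rng.species)
    return RangePolygon(rng.species, geom, rng.method)
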