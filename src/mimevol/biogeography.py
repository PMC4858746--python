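"""Virtual-continent biogeography with a planted model-mimic coupling.

Emulates the statistical structure of the empirical data: clumped species
ranges on a bounded continent, with the regional number of mimic species
drawn so that E[mimic richness] = a + b_model * model richness +
c_total * other richness. The coupling is planted at the level of regional
species pools (Poisson counts), so the slope recovered by a regression of
regional mimic counts on regional model/other richness estimates b_model
directly. Ranges are buffered random walks clipped to the continent —
contiguous like real ranges, with no habitat model behind them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .ranges import RangePolygon

__all__ = ["BiogeographySim", "default_continent", "simulate_virtual_biogeography",
           "GenerationError"]


class GenerationError(RuntimeError):
    pass


def default_continent() -> Polygon:
    """Synthetic continent: an irregular blob spanning roughly 50x56 degrees.

    Stands in for a real coastline; vertices are fixed (radial
    perturbations of an ellipse) so the landmass is identical across runs.
    """
    t = np.linspace(0, 2 * np.pi, 33)[:-1]
    bumps = 1.0 + 0.18 * np.sin(3 * t + 0.7) + 0.12 * np.cos(5 * t - 1.1)
    lon = -60 + 25 * bumps * np.cos(t)
    lat = 0 + 28 * bumps * np.sin(t)
    return Polygon(zip(lon, lat)).buffer(0)


def _random_point_in(poly: Polygon, rng, max_tries: int = 10000) -> Point:
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(max_tries):
        p = Point(
            minx + rng.random() * (maxx - minx),
            miny + rng.random() * (maxy - miny),
        )
        if poly.covers(p):
            return p
    raise GenerationError("continent too small: rejection sampling failed")


def _clumped_range(continent: Polygon, rng, start: "Point | None" = None,
                   n_steps: int = 6, step_deg: float = 2.5,
                   buffer_deg: float = 1.8) -> Polygon:
    """Buffered random walk clipped to the continent."""
    if start is None:
        start = _random_point_in(continent, rng)
    pts = [(start.x, start.y)]
    x, y = start.x, start.y
    for _ in range(n_steps):
        ang = rng.random() * 2 * np.pi
        x += step_deg * np.cos(ang)
        y += step_deg * np.sin(ang)
        pts.append((x, y))
    disks = [Point(p).buffer(buffer_deg, quad_segs=16) for p in pts]
    geom = unary_union(disks).intersection(continent)
    if geom.is_empty:  # walk wandered off land: fall back to the start disk
        geom = start.buffer(buffer_deg, quad_segs=16).intersection(continent)
    return geom


@dataclass
class BiogeographySim:
    """Ground-truth virtual biogeography.

    ``tags`` maps each species to 'model', 'mimic' or 'other';
    ``region_table`` holds the planted regional pools (model/other
    richness and the Poisson mimic count actually drawn).
    """

    continent: Polygon
    ranges: dict                       # species -> shapely geometry
    tags: dict                         # species -> tag
    occurrences: dict                  # species -> (n, 2) lon/lat array
    region_table: pd.DataFrame
    coefficients: dict                 # a, b_model, c_total
    seed: int

    def range_polygons(self) -> list:
        return [
            RangePolygon(sp, geom, "provided") for sp, geom in self.ranges.items()
        ]

    def species(self, tag: "str | None" = None) -> list:
        if tag is None:
            return sorted(self.ranges)
        return sorted(sp for sp, t in self.tags.items() if t == tag)


def simulate_virtual_biogeography(
    n_model: int = 15,
    n_other: int = 25,
    b_model: float = 2.0,
    a: float = 1.0,
    c_total: float = 0.2,
    continent: "Polygon | None" = None,
    region_deg: float = 5.0,
    occ_mean: float = 25.0,
    seed: int = 0,
) -> BiogeographySim:
    """Generate a virtual continent with a known model->mimic coupling.

    Model and 'other' species ranges are placed as random clumps anywhere
    on the continent. The continent is tiled into ``region_deg`` blocks;
    per block k the number of mimic species is Poisson with mean
    max(0, a + b_model * m_k + c_total * o_k), where m_k and o_k count the
    model and other ranges covering the block centroid. Each mimic's range
    is a clump started inside its block. Occurrence points are uniform
    within each range (Poisson(occ_mean) + 1 records per species).
    Bit-identical regeneration under the same seed.
    """
    if n_model < 0 or n_other < 0:
        raise ValueError("species counts must be non-negative")
    rng = np.random.default_rng(seed)
    continent = continent if continent is not None else default_continent()
    if continent.is_empty or continent.area <= 0:
        raise GenerationError("continent polygon is degenerate")

    # model (coral snake) ranges are broad clumps; mimic and 'other'
    # ranges use one tighter, shared clump process so that the two tag
    # classes stay exchangeable under zero coupling (the permutation
    # null shuffles exactly these labels)
    small = dict(n_steps=3, step_deg=1.2, buffer_deg=1.5)
    ranges, tags = {}, {}
    for i in range(n_model):
        sp = f"model_{i:03d}"
        ranges[sp] = _clumped_range(continent, rng)
        tags[sp] = "model"
    for i in range(n_other):
        sp = f"other_{i:03d}"
        ranges[sp] = _clumped_range(continent, rng, **small)
        tags[sp] = "other"

    # regional pools on a block tiling of the continent
    minx, miny, maxx, maxy = continent.bounds
    xs = np.arange(minx, maxx, region_deg)
    ys = np.arange(miny, maxy, region_deg)
    rows = []
    k = 0
    n_mimic_total = 0
    for x0 in xs:
        for y0 in ys:
            block = box(x0, y0, x0 + region_deg, y0 + region_deg)
            cen = block.centroid
            if not continent.covers(cen):
                continue
            m_k = sum(
                ranges[sp].covers(cen) for sp in ranges if tags[sp] == "model"
            )
            o_k = sum(
                ranges[sp].covers(cen) for sp in ranges if tags[sp] == "other"
            )
            mean = max(0.0, a + b_model * m_k + c_total * o_k)
            n_mim = int(rng.poisson(mean))
            rows.append(
                {"region": k, "lon": cen.x, "lat": cen.y,
                 "model_richness": m_k, "other_richness": o_k,
                 "mimic_count": n_mim}
            )
            block_land = block.intersection(continent)
            for _ in range(n_mim):
                sp = f"mimic_{n_mimic_total:03d}"
                start = _random_point_in(block_land, rng)
                ranges[sp] = _clumped_range(continent, rng, start=start, **small)
                tags[sp] = "mimic"
                n_mimic_total += 1
            k += 1
    if not rows:
        raise GenerationError("continent too small for the region tiling")

    occurrences = {}
    for sp in sorted(ranges):
        n_pts = int(rng.poisson(occ_mean)) + 1
        geom = ranges[sp]
        pts = np.array(
            [_random_point_in(geom, rng).coords[0] for _ in range(n_pts)]
        )
        occurrences[sp] = pts

    return BiogeographySim(
        continent=continent,
        ranges=ranges,
        tags=tags,
        occurrences=occurrences,
        region_table=pd.DataFrame(rows),
        coefficients={"a": a, "b_model": b_model, "c_total": c_total},
        seed=seed,
    )
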