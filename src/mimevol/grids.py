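"""Gridded richness and abundance rasters.

Cells are axis-aligned lon/lat squares (2 or 0.5 degrees by default). A
species is present in a cell when its range polygon covers at least half
of the cell's area (inclusive threshold, exact polygon-cell intersection);
cells off land carry no value, and each cell's midpoint serves as its
geographic coordinate. Point records are assigned to cells by half-open
intervals [west, east) x [south, north).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.prepared import prep

__all__ = [
    "GridSpec",
    "RasterGrid",
    "rasterize_presence",
    "richness",
    "subset_cells",
    "abundance_rasters",
    "log2_mimic_model_ratio",
]

COVERAGE_THRESHOLD = 0.5  # fraction of cell area; inclusive
_EPS = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: origin at the south-west corner."""

    origin_lon: float
    origin_lat: float
    nx: int
    ny: int
    resolution: float  # degrees

    @classmethod
    def covering(cls, bounds, resolution: float) -> "GridSpec":
        minx, miny, maxx, maxy = bounds
        ox = np.floor(minx / resolution) * resolution
        oy = np.floor(miny / resolution) * resolution
        nx = int(np.ceil((maxx - ox) / resolution))
        ny = int(np.ceil((maxy - oy) / resolution))
        return cls(float(ox), float(oy), nx, ny, resolution)

    @property
    def cell_area(self) -> float:
        return self.resolution**2

    def x_mid(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.nx) + 0.5) * self.resolution

    def y_mid(self) -> np.ndarray:
        return self.origin_lat + (np.arange(self.ny) + 0.5) * self.resolution

    def cell_box(self, ix: int, iy: int):
        x0 = self.origin_lon + ix * self.resolution
        y0 = self.origin_lat + iy * self.resolution
        return box(x0, y0, x0 + self.resolution, y0 + self.resolution)

    def point_cell(self, lon: float, lat: float) -> tuple:
        """Half-open [west, east) x [south, north) cell membership."""
        ix = int(np.floor((lon - self.origin_lon) / self.resolution))
        iy = int(np.floor((lat - self.origin_lat) / self.resolution))
        return ix, iy

    def onland_mask(self, land) -> np.ndarray:
        """Cells whose midpoint falls on the land polygon."""
        from shapely.geometry import Point

        mask = np.zeros((self.ny, self.nx), dtype=bool)
        prepared = prep(land)
        xm, ym = self.x_mid(), self.y_mid()
        for iy in range(self.ny):
            for ix in range(self.nx):
                mask[iy, ix] = prepared.covers(Point(xm[ix], ym[iy]))
        return mask


@dataclass
class RasterGrid:
    """Per-cell counts on a grid with a land mask (rows = latitude)."""

    spec: GridSpec
    values: np.ndarray  # (ny, nx) int
    onland: np.ndarray  # (ny, nx) bool

    def __post_init__(self):
        self.values = np.where(self.onland, self.values, 0)

    def cell_table(self) -> pd.DataFrame:
        """Long-form table in the deposited-grid dialect (x, y, onland, count)."""
        xm, ym = self.spec.x_mid(), self.spec.y_mid()
        xx, yy = np.meshgrid(xm, ym)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "onland": self.onland.ravel().astype(int),
                "count": self.values.ravel(),
            }
        )


def rasterize_presence(ranges: list, spec: GridSpec, onland: np.ndarray) -> dict:
    """Per-species boolean presence grids by exact >=50% cell coverage.

    Returns ``{species: (ny, nx) bool array}``. Cells off land are always
    absent. Coverage is computed by exact polygon-cell intersection area;
    the threshold is inclusive (exactly half the cell counts as present).
    """
    out = {}
    area = spec.cell_area
    for rp in ranges:
        grid = np.zeros((spec.ny, spec.nx), dtype=bool)
        geom = rp.geometry
        if not geom.is_empty:
            prepared = prep(geom)
            minx, miny, maxx, maxy = geom.bounds
            ix0 = max(0, int(np.floor((minx - spec.origin_lon) / spec.resolution)))
            ix1 = min(spec.nx, int(np.ceil((maxx - spec.origin_lon) / spec.resolution)))
            iy0 = max(0, int(np.floor((miny - spec.origin_lat) / spec.resolution)))
            iy1 = min(spec.ny, int(np.ceil((maxy - spec.origin_lat) / spec.resolution)))
            for iy in range(iy0, iy1):
                for ix in range(ix0, ix1):
                    if not onland[iy, ix]:
                        continue
                    cell = spec.cell_box(ix, iy)
                    if prepared.contains_properly(cell):
                        grid[iy, ix] = True
                    elif prepared.intersects(cell):
                        frac = geom.intersection(cell).area / area
                        grid[iy, ix] = frac >= COVERAGE_THRESHOLD - _EPS
        out[rp.species] = grid
    return out


def richness(presence: dict, spec: GridSpec, onland: np.ndarray,
             species: "list | None" = None) -> RasterGrid:
    """Per-cell species count over a (subset of the) presence grids."""
    if species is None:
        species = list(presence)
    vals = np.zeros((spec.ny, spec.nx), dtype=np.int64)
    for sp in species:
        vals += presence[sp].astype(np.int64)
    return RasterGrid(spec, vals, onland)


def subset_cells(grids: dict, predicate: str) -> pd.DataFrame:
    """Cells containing at least one mimic (or model) species.

    ``grids`` maps set names (must include 'mimic' and 'model') to aligned
    :class:`RasterGrid` objects; the returned table keeps only onland
    cells qualifying under ``predicate`` in {'mimic', 'model'}, with the
    midpoint coordinates and every set's counts.
    """
    if predicate not in {"mimic", "model"}:
        raise ValueError("predicate must be 'mimic' or 'model'")
    names = list(grids)
    ref = grids[predicate]
    spec = ref.spec
    for g in grids.values():
        if g.spec != spec:
            raise ValueError("grids are not aligned")
    keep = ref.onland & (ref.values >= 1)
    xm, ym = spec.x_mid(), spec.y_mid()
    xx, yy = np.meshgrid(xm, ym)
    data = {"x": xx[keep], "y": yy[keep]}
    for name in names:
        data[name] = grids[name].values[keep]
    return pd.DataFrame(data)


def abundance_rasters(occurrences: dict, spec: GridSpec, onland: np.ndarray) -> dict:
    """Per-cell specimen counts per species set.

    ``occurrences`` maps a set name to an (n, 2) lon/lat array of records;
    each record lands in exactly one cell (half-open intervals). Records
    off the grid or off land are dropped.
    """
    out = {}
    for name, pts in occurrences.items():
        vals = np.zeros((spec.ny, spec.nx), dtype=np.int64)
        for lon, lat in np.atleast_2d(pts):
            ix, iy = spec.point_cell(lon, lat)
            if 0 <= ix < spec.nx and 0 <= iy < spec.ny and onland[iy, ix]:
                vals[iy, ix] += 1
        out[name] = RasterGrid(spec, vals, onland)
    return out


def log2_mimic_model_ratio(mimic: RasterGrid, model: RasterGrid) -> np.ndarray:
    """Per-cell log2((mimic + 1) / (model + 1)) specimen-count ratio.

    The +1 pseudocount removes division-by-zero singularities and makes
    empty cells exactly 0.
    """
    if mimic.spec != model.spec:
        raise ValueError("grids are not aligned")
    return np.log2((mimic.values + 1.0) / (model.values + 1.0))
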