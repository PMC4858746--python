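"""Plain-text serialization: CSV tables and GeoJSON geometries.

Grid tables follow the deposited dialect: x = longitude, y = latitude,
onland = presence on land (0/1), then one count column per species set.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .ranges import RangePolygon

__all__ = [
    "write_traits_csv", "read_traits_csv",
    "write_latitudes_csv", "read_latitudes_csv",
    "write_occurrences_csv", "read_occurrences_csv",
    "ranges_to_geojson", "ranges_from_geojson",
    "grid_table", "write_grid_table",
    "write_event_table",
]


def write_traits_csv(path, traits: dict) -> None:
    pd.DataFrame(
        {"species": list(traits), "state": [int(v) for v in traits.values()]}
    ).to_csv(path, index=False)


def read_traits_csv(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["species"].astype(str), df["state"].astype(int)))


def write_latitudes_csv(path, latitudes: dict) -> None:
    pd.DataFrame(
        {"species": list(latitudes), "latitude": list(latitudes.values())}
    ).to_csv(path, index=False)


def read_latitudes_csv(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["species"].astype(str), df["latitude"].astype(float)))


def write_occurrences_csv(path, occurrences: dict) -> None:
    """``occurrences``: species -> (n, 2) lon/lat array."""
    rows = []
    for sp, pts in occurrences.items():
        for lon, lat in np.atleast_2d(pts):
            rows.append({"species": sp, "lon": lon, "lat": lat})
    pd.DataFrame(rows, columns=["species", "lon", "lat"]).to_csv(path, index=False)


def read_occurrences_csv(path) -> dict:
    df = pd.read_csv(path)
    return {
        str(sp): g[["lon", "lat"]].to_numpy()
        for sp, g in df.groupby("species", sort=True)
    }


def ranges_to_geojson(ranges: list, tags: "dict | None" = None) -> str:
    """Serialize range polygons as a GeoJSON FeatureCollection string."""
    feats = []
    for rp in ranges:
        props = {"species": rp.species, "method": rp.method}
        if tags is not None:
            props["tag"] = tags.get(rp.species)
        feats.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(rp.geometry),
                "properties": props,
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": feats})


def ranges_from_geojson(text: str) -> list:
    data = json.loads(text)
    out = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        out.append(
            RangePolygon(
                species=props.get("species", "unknown"),
                geometry=shapely_shape(feat["geometry"]),
                method=props.get("method", "provided"),
            )
        )
    return out


def grid_table(spec, onland: np.ndarray, set_grids: dict) -> pd.DataFrame:
    """Long-form grid table: x, y, onland, one column per species set."""
    xm, ym = spec.x_mid(), spec.y_mid()
    xx, yy = np.meshgrid(xm, ym)
    data = {
        "x": xx.ravel(),
        "y": yy.ravel(),
        "onland": onland.ravel().astype(int),
    }
    for name, grid in set_grids.items():
        vals = grid.values if hasattr(grid, "values") else np.asarray(grid)
        data[name] = vals.ravel()
    return pd.DataFrame(data)


def write_grid_table(path, spec, onland, set_grids) -> None:
    grid_table(spec, onland, set_grids).to_csv(path, index=False)


def write_event_table(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)
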