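"""File formats: GeoTIFF rasters, CSV cell tables, GeoJSON geometries.

Rasters are single-band WGS84 GeoTIFFs.  Georeferencing is carried by the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory with
EPSG:4326), written and parsed with ``tifffile``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import GridSpec, SettledCellFrame

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "frame_to_csv",
    "frame_from_csv",
    "frame_to_geojson",
    "points_to_geojson",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
# key directory: version 1.1.0, 3 keys: model type = geographic (2),
# raster type = pixel-is-area (1), geographic CRS = EPSG:4326
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_geotiff(path, array: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band georeferenced TIFF on the given grid."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    if array.dtype == bool:
        array = array.astype(np.uint8)
    s = grid.cell_size
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]
    tifffile.imwrite(str(path), array, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band GeoTIFF and reconstruct its grid geometry."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path} is not georeferenced (missing GeoTIFF tags)")
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_MODEL_TIEPOINT].value
        origin_x = tie[3] - tie[0] * sx
        origin_y = tie[4] + tie[1] * sy
    if not np.isclose(sx, sy):
        raise ValueError(f"non-square pixels ({sx} x {sy}) are not supported")
    grid = GridSpec(
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=float(sx),
        n_rows=array.shape[0],
        n_cols=array.shape[1],
    )
    return array, grid


_FRAME_COLUMNS = ["cell_id", "row", "col", "centroid_lon", "centroid_lat", "population"]


def frame_to_csv(frame: SettledCellFrame, path) -> None:
    """Serialize the cell table; grid geometry goes in a JSON sidecar."""
    frame.cells[_FRAME_COLUMNS].to_csv(path, index=False)
    sidecar = Path(str(path)).with_suffix(".grid.json")
    sidecar.write_text(
        json.dumps(
            {
                "origin_x": frame.grid.origin_x,
                "origin_y": frame.grid.origin_y,
                "cell_size": frame.grid.cell_size,
                "n_rows": frame.grid.n_rows,
                "n_cols": frame.grid.n_cols,
            },
            indent=2,
        )
    )


def frame_from_csv(path, grid: GridSpec | None = None) -> SettledCellFrame:
    if grid is None:
        sidecar = Path(str(path)).with_suffix(".grid.json")
        if not sidecar.exists():
            raise ValueError(f"no GridSpec given and sidecar {sidecar} not found")
        grid = GridSpec(**json.loads(sidecar.read_text()))
    cells = pd.read_csv(path)
    cells["cell_id"] = cells["cell_id"].astype(int)
    cells["row"] = cells["row"].astype(int)
    cells["col"] = cells["col"].astype(int)
    return SettledCellFrame(grid=grid, cells=cells)


def _feature(geometry: dict, properties: dict) -> dict:
    return {"type": "Feature", "geometry": geometry, "properties": properties}


def frame_to_geojson(frame: SettledCellFrame, path) -> None:
    """Write settled-cell rectangles as a GeoJSON FeatureCollection."""
    features = []
    for rec in frame.cells.itertuples(index=False):
        minx, miny, maxx, maxy = frame.grid.cell_bounds(rec.row, rec.col)
        ring = [[minx, miny], [maxx, miny], [maxx, maxy], [minx, maxy], [minx, miny]]
        features.append(
            _feature(
                {"type": "Polygon", "coordinates": [ring]},
                {"cell_id": int(rec.cell_id), "population": float(rec.population)},
            )
        )
    Path(str(path)).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def points_to_geojson(table: pd.DataFrame, path) -> None:
    """Write rows with centroid_lon/centroid_lat as GeoJSON points.

    All other columns become feature properties (the sampled-locations map
    product: cell centroids with their design weights).
    """
    prop_cols = [c for c in table.columns if c not in ("centroid_lon", "centroid_lat")]
    features = []
    for rec in table.to_dict("records"):
        props = {}
        for c in prop_cols:
            v = rec[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            props[c] = v
        features.append(
            _feature(
                {
                    "type": "Point",
                    "coordinates": [float(rec["centroid_lon"]), float(rec["centroid_lat"])],
                },
                props,
            )
        )
    Path(str(path)).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
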