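"""Gridded sampling frame: settled cells with population counts.

The sampling frame for a grid-based household survey design is the set of
*settled* grid cells — cells intersected by at least one settlement polygon —
each carrying a population count ``X(l)``.  The frame is the discrete support
of a bi-dimensional random field: population counts show spatial trends,
spatial autocorrelation and stratification, and are defined only on settled
cells.

Grid convention: cell ``(i, j)`` is 0-based, row-major from the north-west
corner.  The cell rectangle is half-open,
``[x0 + j*s, x0 + (j+1)*s) x (y0 - (i+1)*s, y0 - i*s]``,
so every point of the plane belongs to at most one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.validation import explain_validity

__all__ = ["GridSpec", "SettledCellFrame", "rasterize_settlements", "build_frame"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the reference grid.

    Parameters
    ----------
    origin_x : float
        Longitude of the west edge of the grid (degrees).
    origin_y : float
        Latitude of the *north* edge of the grid (degrees); rows count
        southward.
    cell_size : float
        Cell side in degrees.  3 arc-seconds (1/1200 degree, roughly 90 m at
        the equator) is the conventional resolution for settlement grids.
    n_rows, n_cols : int
        Grid dimensions.
    """

    origin_x: float
    origin_y: float
    cell_size: float = 1.0 / 1200.0
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of cell (i, j)."""
        s = self.cell_size
        x0 = self.origin_x + j * s
        y1 = self.origin_y - i * s
        return (x0, y1 - s, x0 + s, y1)

    def cell_centroid(self, i, j):
        s = self.cell_size
        return (
            self.origin_x + (np.asarray(j) + 0.5) * s,
            self.origin_y - (np.asarray(i) + 0.5) * s,
        )

    def locate(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell containing point (x, y) under the half-open convention."""
        j = int(np.floor((x - self.origin_x) / self.cell_size))
        # row interval is (bottom, top]: a y on a shared edge belongs to the
        # row below, which floor() delivers directly
        i = int(np.floor((self.origin_y - y) / self.cell_size))
        if 0 <= i < self.n_rows and 0 <= j < self.n_cols:
            return (i, j)
        return None

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )


@dataclass
class SettledCellFrame:
    """The sampling frame: one record per settled cell, row-major order.

    ``cells`` is a DataFrame with columns
    ``cell_id, row, col, centroid_lon, centroid_lat, population``.
    ``cell_id = row * n_cols + col`` is stable under serialization.
    """

    grid: GridSpec
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"cell_id", "row", "col", "centroid_lon", "centroid_lat", "population"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"frame table missing columns: {sorted(missing)}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")
        if (self.cells["population"] < 0).any():
            raise ValueError("population counts must be non-negative")
        if len(self.cells) > self.grid.n_rows * self.grid.n_cols:
            raise ValueError("more settled cells than grid cells")

    @property
    def m(self) -> int:
        """Total number of settled cells."""
        return len(self.cells)

    @property
    def populations(self) -> np.ndarray:
        return self.cells["population"].to_numpy(dtype=float)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy(dtype=int)

    def require_nonempty(self, operation: str = "operation") -> None:
        if self.m == 0:
            raise ValueError(f"{operation} requires a non-empty sampling frame")


def rasterize_settlements(polygons, grid: GridSpec) -> np.ndarray:
    """Flag grid cells intersected by at least one settlement polygon.

    A cell is settled iff some polygon intersects its rectangle with positive
    area; a polygon touching only a cell edge does not settle it.  Polygons
    entirely outside the grid extent are ignored with a warning; invalid
    geometries raise, naming the offending feature index.

    Returns a boolean (n_rows, n_cols) mask.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    polygons = list(polygons)
    if not polygons:
        return mask

    s = grid.cell_size
    gx0, gy0 = grid.origin_x, grid.origin_y
    extent_box = box(*grid.extent)
    n_outside = 0
    for idx, poly in enumerate(polygons):
        if poly is None or poly.is_empty:
            continue
        if not poly.is_valid:
            raise ValueError(
                f"invalid settlement geometry at feature index {idx}: "
                f"{explain_validity(poly)}"
            )
        if not poly.intersects(extent_box) or poly.intersection(extent_box).area == 0:
            n_outside += 1
            continue
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(int(np.floor((minx - gx0) / s)), 0)
        j1 = min(int(np.floor((maxx - gx0) / s)), grid.n_cols - 1)
        i0 = max(int(np.floor((gy0 - maxy) / s)), 0)
        i1 = min(int(np.floor((gy0 - miny) / s)), grid.n_rows - 1)
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                if mask[i, j]:
                    continue
                cell = box(*grid.cell_bounds(i, j))
                if poly.intersects(cell) and poly.intersection(cell).area > 0:
                    mask[i, j] = True
    if n_outside:
        warnings.warn(
            f"{n_outside} settlement polygon(s) outside the grid extent were ignored",
            stacklevel=2,
        )
    return mask


def build_frame(
    settled_mask: np.ndarray, population_raster: np.ndarray, grid: GridSpec
) -> SettledCellFrame:
    """Assemble the settled-cell frame from a mask and a population raster.

    One record per settled cell in row-major order, population copied from the
    raster.  No-data (NaN) population at a settled cell becomes 0 with a
    warning: the cell is settled by evidence, and a zero count simply removes
    it from PPS draws without breaking frame completeness.
    """
    settled_mask = np.asarray(settled_mask, dtype=bool)
    population_raster = np.asarray(population_raster, dtype=float)
    if settled_mask.shape != grid.shape or population_raster.shape != grid.shape:
        raise ValueError(
            f"shape mismatch: mask {settled_mask.shape}, population "
            f"{population_raster.shape}, grid {grid.shape}"
        )
    rows, cols = np.nonzero(settled_mask)  # np.nonzero is row-major
    pop = population_raster[rows, cols]
    n_nodata = int(np.isnan(pop).sum())
    if n_nodata:
        warnings.warn(
            f"{n_nodata} settled cell(s) with no-data population set to 0",
            stacklevel=2,
        )
        pop = np.nan_to_num(pop, nan=0.0)
    if (pop < 0).any():
        bad = int(np.argmax(pop < 0))
        raise ValueError(
            f"negative population {pop[bad]} at settled cell "
            f"(row={rows[bad]}, col={cols[bad]})"
        )
    lon, lat = grid.cell_centroid(rows, cols)
    cells = pd.DataFrame(
        {
            "cell_id": rows * grid.n_cols + cols,
            "row": rows,
            "col": cols,
            "centroid_lon": np.atleast_1d(lon),
            "centroid_lat": np.atleast_1d(lat),
            "population": pop,
        }
    )
    return SettledCellFrame(grid=grid, cells=cells)
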