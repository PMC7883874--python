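"""Core spatial containers: point clouds, single-band raster grids, zonal masks.

Conventions used throughout the package:

* Coordinates are metric, in a projected CRS (any planar system; the CRS id
  is carried along as an opaque string and never interpreted).
* A :class:`RasterGrid` stores its origin at the *lower-left* corner; row 0 is
  the southernmost row.  Cell ``(i, j)`` covers the half-open square
  ``[x0 + j*c, x0 + (j+1)*c) x [y0 + i*c, y0 + (i+1)*c)`` and its value is
  located at the cell centre.
* Missing cells are ``NaN`` in memory; an explicit nodata marker is only used
  at the file-format boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon


@dataclass
class PointCloud:
    """Georeferenced x, y, z samples of a canopy or ground surface."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray | None = None
    classification: np.ndarray | None = None  # LAS-style: 2 = ground

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x.size == 0:
            raise ValueError("point cloud must contain at least one point")
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have identical shapes")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                and np.isfinite(self.z).all()):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.x.size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the points."""
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            None if self.intensity is None else self.intensity[mask],
            None if self.classification is None else self.classification[mask],
        )


@dataclass
class RasterGrid:
    """Single-band georeferenced grid (DSM, DEM, CSH, band or texture image)."""

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray
    crs: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        c = self.cell_size
        return (self.x0, self.y0, self.x0 + self.n_cols * c, self.y0 + self.n_rows * c)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def geometry_repr(self) -> str:
        return (f"origin=({self.x0:.4f},{self.y0:.4f}) cell={self.cell_size:.4f} "
                f"shape={self.values.shape}")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid-shaped (xs, ys) of all cell centres (row 0 = south)."""
        c = self.cell_size
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * c
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * c
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells containing the points (half-open membership)."""
        j = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        i = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return i, j

    def crop(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "RasterGrid":
        """Sub-grid aligned to this grid covering at least the given bounds."""
        c = self.cell_size
        j0 = max(0, int(np.floor((xmin - self.x0) / c)))
        i0 = max(0, int(np.floor((ymin - self.y0) / c)))
        j1 = min(self.n_cols, int(np.ceil((xmax - self.x0) / c)))
        i1 = min(self.n_rows, int(np.ceil((ymax - self.y0) / c)))
        if i1 <= i0 or j1 <= j0:
            raise ValueError("crop window does not intersect the raster")
        return RasterGrid(self.x0 + j0 * c, self.y0 + i0 * c, c,
                          self.values[i0:i1, j0:j1].copy(), self.crs)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.x0, self.y0, self.cell_size,
                          np.asarray(values, dtype=float), self.crs)


@dataclass
class GridSpec:
    """Target geometry for rasterisation."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "local"

    @classmethod
    def from_bounds(cls, xmin: float, ymin: float, xmax: float, ymax: float,
                    cell_size: float, crs: str = "local") -> "GridSpec":
        n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size - 1e-9)))
        n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size - 1e-9)))
        return cls(xmin, ymin, cell_size, n_rows, n_cols, crs)

    def empty_grid(self, fill: float = np.nan) -> RasterGrid:
        return RasterGrid(self.x0, self.y0, self.cell_size,
                          np.full((self.n_rows, self.n_cols), fill), self.crs)


def trim_strip(polygon: Polygon, strip_m: float) -> Polygon:
    """Remove the sampling strip from the start of a plot polygon.

    The strip is the first ``strip_m`` metres of the plot along its *long*
    axis (the destructively sampled end, by convention the lower end of the
    long axis).  Operates on the polygon envelope, which is exact for the
    axis-aligned rectangular plots this package works with.
    """
    if strip_m <= 0:
        return polygon
    xmin, ymin, xmax, ymax = polygon.bounds
    if (xmax - xmin) >= (ymax - ymin):
        clipped = shapely.box(xmin + strip_m, ymin, xmax, ymax)
    else:
        clipped = shapely.box(xmin, ymin + strip_m, xmax, ymax)
    out = polygon.intersection(clipped)
    if out.is_empty:
        raise ValueError("excluded strip removes the whole polygon")
    return out


def zonal_mask(grid: RasterGrid, polygon: Polygon,
               excluded_strip_m: float = 0.0) -> np.ndarray:
    """Boolean mask of cells whose centres lie inside the (trimmed) polygon."""
    poly = trim_strip(polygon, excluded_strip_m)
    xs, ys = grid.cell_centers()
    return shapely.contains_xy(poly, xs, ys)


def zonal_mean(grid: RasterGrid, polygon: Polygon,
               excluded_strip_m: float = 0.0) -> float:
    """Mean of valid (non-NaN) cells inside the trimmed polygon."""
    mask = zonal_mask(grid, polygon, excluded_strip_m)
    vals = grid.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid cells inside the polygon")
    return float(vals.mean())
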