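"""Crop surface height (CSH) extraction from TLS point clouds.

The workflow mirrors standard sward-height processing: the vegetated point
cloud is gridded to a digital surface model (DSM), a bare-ground scan gives
the digital elevation model (DEM), and the per-cell difference

    CSH = DSM - DEM

is summarised per plot by fifteen height metrics (mean, min, max, median,
variance, sd, range, mode, skewness, kurtosis, canopy height relief and the
25/75/90/95 % percentiles).

Numerical conventions (documented because they shift results on small
samples): percentiles use linear interpolation between order statistics
(type 7); skewness is Fisher-Pearson g1 and kurtosis is excess g2 (population
moment ratios); variance/sd are sample statistics (ddof = 1); the mode is the
midpoint of the most populated 1 cm histogram bin over [0, max], first bin on
ties.  Negative CSH cells are clamped to zero (ground-noise interpretation)
and counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from .core import GridSpec, PointCloud, RasterGrid, zonal_mask

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "mean", "min", "max", "median", "variance", "sd", "range", "mode",
    "skewness", "kurtosis", "relief", "p25", "p75", "p90", "p95",
)


@dataclass
class CSHMetrics:
    """The fifteen per-plot crop surface height metrics."""

    mean: float
    min: float
    max: float
    median: float
    variance: float
    sd: float
    range: float
    mode: float
    skewness: float
    kurtosis: float
    relief: float
    p25: float
    p75: float
    p90: float
    p95: float

    def to_dict(self, prefix: str = "csh_") -> dict[str, float]:
        return {prefix + name: getattr(self, name) for name in METRIC_NAMES}


class CSHResult(NamedTuple):
    grid: RasterGrid
    n_clamped: int


def rasterize_surface(cloud: PointCloud, grid: GridSpec,
                      aggregator: str = "max") -> RasterGrid:
    """Grid the z-values of a point cloud.

    Each cell aggregates the z-values of the points it contains (half-open
    cell intervals; points exactly on the outer right/top grid edge are
    assigned to the last cell, as in histogram binning).  Empty cells are
    NaN.

    Parameters
    ----------
    aggregator : {"max", "mean", "p95"}
        ``max`` is the conventional top-of-canopy surface; ``mean`` gives the
        smoother surface used for texture extraction.
    """
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty point cloud")
    out = grid.empty_grid()
    c = grid.cell_size
    xmax = grid.x0 + grid.n_cols * c
    ymax = grid.y0 + grid.n_rows * c
    if (cloud.x.min() < grid.x0 or cloud.y.min() < grid.y0
            or cloud.x.max() > xmax or cloud.y.max() > ymax):
        raise ValueError("grid does not cover the cloud bounding box")
    j = np.floor((cloud.x - grid.x0) / c).astype(int)
    i = np.floor((cloud.y - grid.y0) / c).astype(int)
    j = np.minimum(j, grid.n_cols - 1)  # outer-edge points into last cell
    i = np.minimum(i, grid.n_rows - 1)
    flat = i * grid.n_cols + j

    if aggregator == "max":
        agg = np.full(grid.n_rows * grid.n_cols, -np.inf)
        np.maximum.at(agg, flat, cloud.z)
        agg[np.isinf(agg)] = np.nan
    elif aggregator == "mean":
        total = np.zeros(grid.n_rows * grid.n_cols)
        count = np.zeros(grid.n_rows * grid.n_cols)
        np.add.at(total, flat, cloud.z)
        np.add.at(count, flat, 1.0)
        with np.errstate(invalid="ignore"):
            agg = total / count
        agg[count == 0] = np.nan
    elif aggregator == "p95":
        q = pd.Series(cloud.z).groupby(flat).quantile(0.95)
        agg = np.full(grid.n_rows * grid.n_cols, np.nan)
        agg[q.index.to_numpy()] = q.to_numpy()
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")

    values = agg.reshape(grid.n_rows, grid.n_cols)
    if not np.isfinite(values).any():
        raise ValueError("rasterization produced an all-empty grid")
    out.values[:] = values
    return out


def compute_csh(dsm: RasterGrid, dem: RasterGrid,
                clamp_negative: bool = True) -> CSHResult:
    """Cellwise canopy height: DSM minus DEM on identical grid geometry.

    NaN in either input propagates.  Negative heights are clamped to zero
    (they are ground-measurement noise) and counted.
    """
    if not dsm.same_geometry(dem):
        raise ValueError(
            "DSM and DEM geometries differ: "
            f"DSM {dsm.geometry_repr()} vs DEM {dem.geometry_repr()}")
    csh = dsm.values - dem.values
    n_clamped = 0
    if clamp_negative:
        neg = csh < 0
        n_clamped = int(np.count_nonzero(neg & np.isfinite(csh)))
        if n_clamped:
            logger.info("clamped %d negative CSH cells to 0", n_clamped)
        csh = np.where(neg, 0.0, csh)
    return CSHResult(dsm.copy_with(csh), n_clamped)


def canopy_height_relief(values: np.ndarray) -> float:
    """(mean - min) / (max - min); 0 for a flat canopy.

    A vertical-distribution descriptor in [0, 1]: low values indicate most
    of the canopy sits near the minimum height.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("relief needs at least two height values")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return 0.0
    return float((values.mean() - vmin) / (vmax - vmin))


def _mode_1cm(values: np.ndarray, bin_width: float = 0.01) -> float:
    """Midpoint of the most populated histogram bin over [0, max]."""
    vmax = float(values.max())
    if vmax <= 0:
        return 0.0
    n_bins = max(1, int(np.ceil(vmax / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, n_bins * bin_width))
    k = int(np.argmax(counts))  # first bin on ties
    return float((edges[k] + edges[k + 1]) / 2)


def metrics_from_values(values: np.ndarray) -> CSHMetrics:
    """The fifteen CSH metrics of a pooled set of cell heights."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two valid CSH cells")
    vmin, vmax = float(values.min()), float(values.max())
    degenerate = vmax == vmin
    if degenerate:
        warnings.warn("constant CSH: relief, skewness and kurtosis set to 0",
                      stacklevel=2)
        skew = kurt = relief = 0.0
    else:
        skew = float(stats.skew(values, bias=True))
        kurt = float(stats.kurtosis(values, fisher=True, bias=True))
        relief = canopy_height_relief(values)
    p25, p75, p90, p95 = (float(v) for v in
                          np.percentile(values, [25, 75, 90, 95]))
    variance = float(values.var(ddof=1))
    return CSHMetrics(
        mean=float(values.mean()), min=vmin, max=vmax,
        median=float(np.median(values)), variance=variance,
        sd=float(np.sqrt(variance)), range=vmax - vmin,
        mode=_mode_1cm(values), skewness=skew, kurtosis=kurt, relief=relief,
        p25=p25, p75=p75, p90=p90, p95=p95,
    )


def plot_csh_metrics(csh: RasterGrid, polygon: Polygon,
                     excluded_strip_m: float = 0.0) -> CSHMetrics:
    """CSH metrics pooled over all valid cells whose centres fall inside the
    polygon minus the excluded sampling strip."""
    mask = zonal_mask(csh, polygon, excluded_strip_m)
    return metrics_from_values(csh.values[mask])
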