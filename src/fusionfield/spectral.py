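"""Per-plot band statistics and vegetation indices.

Band reflectances (green, red, red edge, NIR) are averaged per plot by zonal
masking, and the vegetation indices are computed *from the plot-mean
reflectances* (not per pixel and then averaged; a flag on the pipeline
enables the per-pixel variant for sensitivity analysis).

The index set lives in a declarative registry mapping a name to a formula
over the band means ``{G, R, RE, N}``, so the set can be replaced or extended
without touching any code path.  The default registry carries thirteen
widely used indices spanning the normalized-difference, ratio and
soil-adjusted families.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping

import numpy as np
from shapely.geometry import Polygon

from .core import RasterGrid, zonal_mean

BAND_NAMES = ("green", "red", "red_edge", "nir")

# name -> formula over (G, R, RE, N); all unitless reflectances in [0, 1]
VI_REGISTRY: dict[str, Callable[[float, float, float, float], float]] = {
    "NDVI": lambda G, R, RE, N: (N - R) / (N + R),
    "GNDVI": lambda G, R, RE, N: (N - G) / (N + G),
    "NDRE": lambda G, R, RE, N: (N - RE) / (N + RE),
    "RVI": lambda G, R, RE, N: N / R,
    "GRVI": lambda G, R, RE, N: (G - R) / (G + R),
    "CIgreen": lambda G, R, RE, N: N / G - 1.0,
    "CIrededge": lambda G, R, RE, N: N / RE - 1.0,
    "SAVI": lambda G, R, RE, N: 1.5 * (N - R) / (N + R + 0.5),
    "OSAVI": lambda G, R, RE, N: (N - R) / (N + R + 0.16),
    "MSAVI2": lambda G, R, RE, N:
        (2 * N + 1 - np.sqrt((2 * N + 1) ** 2 - 8 * (N - R))) / 2,
    "EVI2": lambda G, R, RE, N: 2.5 * (N - R) / (N + 2.4 * R + 1),
    "RDVI": lambda G, R, RE, N: (N - R) / np.sqrt(N + R),
    "MCARI": lambda G, R, RE, N: ((RE - R) - 0.2 * (RE - G)) * (RE / R),
}


def zonal_band_means(bands: Mapping[str, RasterGrid], polygon: Polygon,
                     excluded_strip_m: float = 0.0) -> dict[str, float]:
    """Mean reflectance per band over valid cells inside the trimmed polygon.

    All four bands must be present and co-registered (identical geometry).
    """
    missing = [b for b in BAND_NAMES if b not in bands]
    if missing:
        raise ValueError(f"missing bands: {missing}")
    ref = bands[BAND_NAMES[0]]
    for name in BAND_NAMES[1:]:
        if not bands[name].same_geometry(ref):
            raise ValueError(f"band {name!r} is not co-registered with "
                             f"{BAND_NAMES[0]!r}")
    return {name: zonal_mean(bands[name], polygon, excluded_strip_m)
            for name in BAND_NAMES}


def compute_vis(band_means: Mapping[str, float],
                registry: Mapping[str, Callable] | None = None) -> dict[str, float]:
    """Vegetation indices from the four band means.

    A vanishing denominator yields NaN for that index (with a warning), not
    an exception, so one degenerate plot cannot abort a batch run.
    """
    registry = VI_REGISTRY if registry is None else registry
    for name in BAND_NAMES:
        if name not in band_means:
            raise ValueError(f"band mean {name!r} missing")
    G, R = band_means["green"], band_means["red"]
    RE, N = band_means["red_edge"], band_means["nir"]
    out: dict[str, float] = {}
    for name, formula in registry.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            try:
                val = float(formula(G, R, RE, N))
            except ZeroDivisionError:
                val = np.nan
        if not np.isfinite(val):
            warnings.warn(f"{name}: undefined for band means "
                          f"G={G} R={R} RE={RE} N={N}", stacklevel=2)
            val = np.nan
        out[name] = val
    return out


def spectral_record(bands: Mapping[str, RasterGrid], polygon: Polygon,
                    excluded_strip_m: float = 0.0) -> dict[str, float]:
    """Band means plus vegetation indices for one plot."""
    means = zonal_band_means(bands, polygon, excluded_strip_m)
    record = {f"band_{k}": v for k, v in means.items()}
    record.update(compute_vis(means))
    return record
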