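"""Gray-level co-occurrence (GLCM) texture features.

A GLCM tabulates how often two gray levels co-occur at a fixed pixel offset;
its scalar summaries (Haralick features) describe local image texture.  This
module computes the eight features used for sward structure description —
energy, entropy, correlation, inverse difference moment, inertia (contrast),
cluster shade, cluster prominence and Haralick correlation — per pixel over a
sliding window, for the mean-CSH raster and the four spectral bands, and
averages each texture image per plot.

Defaults mirror the "simple" texture set of the Orfeo Toolbox lineage:
window radius 2 (5x5), a single (0, 1) offset with symmetric counting, and
8 gray levels after linear rescaling of the input range.  Entropy is in bits.

Two conventions exist for *Haralick correlation*; both are available:

* ``"marginal_sums"`` (default, the Orfeo/ITK convention): with the marginal
  row sums r_i = sum_j p(i, j),  HC = (sum_ij i*j*p - mu_t^2) / sigma_t^2
  where mu_t and sigma_t are the plain mean and (population) standard
  deviation of the G values r_i.
* ``"f3"`` (the textbook definition): (sum_ij i*j*p - mu_x*mu_y) /
  (sigma_x*sigma_y) with level-weighted marginal moments.

The two differ numerically; the package treats the convention as a parameter
so either lineage can be reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .core import RasterGrid, zonal_mean

FEATURE_NAMES = (
    "energy", "entropy", "correlation", "inverse_difference_moment",
    "inertia", "cluster_shade", "cluster_prominence", "haralick_correlation",
)

_EPS = 1e-12


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities for a set of offsets."""

    p: np.ndarray  # G x G, sums to 1
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("GLCM must be square")
        if (self.p < 0).any():
            raise ValueError("GLCM probabilities must be non-negative")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM probabilities sum to {total}, not 1")

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


@dataclass
class TextureVector:
    """The eight Haralick features of one GLCM (or one plot average)."""

    energy: float
    entropy: float
    correlation: float
    inverse_difference_moment: float
    inertia: float
    cluster_shade: float
    cluster_prominence: float
    haralick_correlation: float
    layer: str = ""

    def to_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + name: getattr(self, name) for name in FEATURE_NAMES}


def quantize(raster: RasterGrid | np.ndarray, n_levels: int = 8,
             value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Linear binning of raster values into integer levels 0..G-1.

    ``value_range=None`` uses the min/max of the valid cells (a constant
    raster then maps everything to level 0, with a warning).  Out-of-range
    values are clipped into the outer bins; the range maximum itself maps to
    level G-1, never G.  Nodata (NaN) cells become -1.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    vals = raster.values if isinstance(raster, RasterGrid) else np.asarray(raster, float)
    valid = np.isfinite(vals)
    if value_range is None:
        if not valid.any():
            raise ValueError("cannot auto-range an all-nodata raster")
        lo, hi = float(vals[valid].min()), float(vals[valid].max())
        if hi == lo:
            warnings.warn("constant raster: all cells map to level 0", stacklevel=2)
            hi = lo + 1.0
    else:
        lo, hi = value_range
        if not hi > lo:
            raise ValueError("value_range min must be below max")
    with np.errstate(invalid="ignore"):
        levels = np.floor((vals - lo) / (hi - lo) * n_levels)
    levels = np.clip(levels, 0, n_levels - 1)
    out = np.where(valid, levels, -1)
    return out.astype(np.int64)


def glcm(window: np.ndarray, offsets: list[tuple[int, int]] = [(0, 1)],
         symmetric: bool = True, n_levels: int | None = None) -> GLCMatrix:
    """Co-occurrence matrix of an integer window (-1 marks invalid cells).

    All in-window pixel pairs separated by each ``(dy, dx)`` offset are
    counted; symmetric counting adds the transposed pairs; the counts are
    normalized to probabilities.
    """
    window = np.asarray(window)
    if not np.issubdtype(window.dtype, np.integer):
        raise TypeError("glcm expects a pre-quantized integer window")
    G = int(window.max()) + 1 if n_levels is None else n_levels
    if G < 1:
        raise ValueError("window contains no valid levels")
    counts = np.zeros((G, G))
    H, W = window.shape
    for dy, dx in offsets:
        y0a, y1a = max(0, -dy), H - max(0, dy)
        x0a, x1a = max(0, -dx), W - max(0, dx)
        if y1a <= y0a or x1a <= x0a:
            continue
        a = window[y0a:y1a, x0a:x1a]
        b = window[y0a + dy:y1a + dy, x0a + dx:x1a + dx]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pair for the given offsets")
    return GLCMatrix(counts / total, tuple(map(tuple, offsets)), symmetric)


def haralick_features(m: GLCMatrix, *, entropy_base: float = 2.0,
                      haralick_corr: str = "marginal_sums",
                      layer: str = "") -> TextureVector:
    """The eight Haralick features of a GLCM.

    Degenerate-variance cases (constant window) return 0 for correlation and
    Haralick correlation, with a warning.
    """
    p = m.p
    G = m.n_levels
    i = np.arange(G)[:, None].astype(float)
    j = np.arange(G)[None, :].astype(float)

    energy = float((p ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(entropy_base))).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lev = np.arange(G, dtype=float)
    mu_x = float((lev * px).sum())
    mu_y = float((lev * py).sum())
    var_x = float(((lev - mu_x) ** 2 * px).sum())
    var_y = float(((lev - mu_y) ** 2 * py).sum())
    sum_ij_p = float((i * j * p).sum())
    if var_x <= _EPS or var_y <= _EPS:
        warnings.warn("degenerate GLCM marginals: correlation set to 0",
                      stacklevel=2)
        correlation = 0.0
    else:
        correlation = (sum_ij_p - mu_x * mu_y) / np.sqrt(var_x * var_y)

    dev = (i - mu_x) + (j - mu_y)
    shade = float((dev ** 3 * p).sum())
    prominence = float((dev ** 4 * p).sum())

    if haralick_corr == "marginal_sums":
        mu_t = float(px.mean())
        var_t = float(px.var())  # population variance of the marginal sums
        if var_t <= _EPS:
            warnings.warn("uniform GLCM marginal sums: Haralick correlation "
                          "set to 0", stacklevel=2)
            hcorr = 0.0
        else:
            hcorr = (sum_ij_p - mu_t ** 2) / var_t
    elif haralick_corr == "f3":
        if var_x <= _EPS or var_y <= _EPS:
            hcorr = 0.0
        else:
            hcorr = (sum_ij_p - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        raise ValueError(f"unknown haralick_corr convention {haralick_corr!r}")

    return TextureVector(energy, entropy, float(correlation), idm, inertia,
                         shade, prominence, float(hcorr), layer=layer)


def _integral(a: np.ndarray) -> np.ndarray:
    """Zero-padded 2-D summed-area table."""
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=s[1:, 1:])
    return s


def _window_pair_counts(levels: np.ndarray, radius: int,
                        offsets: list[tuple[int, int]], symmetric: bool,
                        G: int) -> np.ndarray:
    """Per-pixel GLCM counts, shape (G, G, H, W), truncated at raster edges.

    For the window centred at (y, x) a pair (anchor u,v -> partner
    u+dy, v+dx) is counted iff both pixels lie in the clipped window and both
    carry a valid level.
    """
    H, W = levels.shape
    counts = np.zeros((G, G, H, W))
    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    offs = list(offsets)
    if symmetric:
        offs = offs + [(-dy, -dx) for dy, dx in offsets]
    for dy, dx in offs:
        y0a, y1a = max(0, -dy), H - max(0, dy)
        x0a, x1a = max(0, -dx), W - max(0, dx)
        if y1a <= y0a or x1a <= x0a:
            continue
        # anchor rows allowed for the window at (y, x):
        r0y = np.clip(yy - radius + max(0, -dy), 0, H)
        r1y = np.clip(yy + radius - max(0, dy) + 1, 0, H)
        r0x = np.clip(xx - radius + max(0, -dx), 0, W)
        r1x = np.clip(xx + radius - max(0, dx) + 1, 0, W)
        a = levels[y0a:y1a, x0a:x1a]
        b = levels[y0a + dy:y1a + dy, x0a + dx:x1a + dx]
        ok = (a >= 0) & (b >= 0)
        for gi in range(G):
            ai = ok & (a == gi)
            if not ai.any():
                continue
            for gj in range(G):
                ind = ai & (b == gj)
                if not ind.any():
                    continue
                full = np.zeros((H, W))
                full[y0a:y1a, x0a:x1a] = ind
                S = _integral(full)
                r1yc = np.maximum(r1y, r0y)
                r1xc = np.maximum(r1x, r0x)
                counts[gi, gj] += (S[r1yc, r1xc] - S[r0y, r1xc]
                                   - S[r1yc, r0x] + S[r0y, r0x])
    return counts


def texture_image(raster: RasterGrid, radius: int = 2,
                  offsets: list[tuple[int, int]] = [(0, 1)],
                  n_levels: int = 8,
                  value_range: tuple[float, float] | None = None,
                  symmetric: bool = True, entropy_base: float = 2.0,
                  haralick_corr: str = "marginal_sums") -> dict[str, RasterGrid]:
    """Per-pixel Haralick features over a sliding (2*radius+1)^2 window.

    Edge pixels use the truncated in-bounds window; nodata pixels never
    contribute to pairs and receive NaN features themselves.  Output grids
    inherit the input geometry.
    """
    if raster.n_rows < 2 or raster.n_cols < 2:
        raise ValueError("raster must be at least 2x2 for texture extraction")
    levels = quantize(raster, n_levels, value_range)
    G = n_levels
    counts = _window_pair_counts(levels, radius, offsets, symmetric, G)
    T = counts.sum(axis=(0, 1))
    valid = (T > 0) & (levels >= 0)
    Tsafe = np.where(T > 0, T, 1.0)
    P = counts / Tsafe  # (G, G, H, W)

    i = np.arange(G, dtype=float)[:, None, None, None]
    j = np.arange(G, dtype=float)[None, :, None, None]

    energy = (P ** 2).sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    entropy = -(P * logp).sum(axis=(0, 1)) / np.log(entropy_base)
    inertia = ((i - j) ** 2 * P).sum(axis=(0, 1))
    idm = (P / (1.0 + (i - j) ** 2)).sum(axis=(0, 1))

    px = P.sum(axis=1)  # (G, H, W) marginal row sums r_i
    py = P.sum(axis=0)
    lev = np.arange(G, dtype=float)[:, None, None]
    mu_x = (lev * px).sum(axis=0)
    mu_y = (lev * py).sum(axis=0)
    var_x = ((lev - mu_x) ** 2 * px).sum(axis=0)
    var_y = ((lev - mu_y) ** 2 * py).sum(axis=0)
    sum_ij_p = (i * j * P).sum(axis=(0, 1))
    sig = np.sqrt(var_x * var_y)
    correlation = np.where(sig > _EPS, (sum_ij_p - mu_x * mu_y)
                           / np.where(sig > _EPS, sig, 1.0), 0.0)

    dev = (i - mu_x) + (j - mu_y)
    shade = (dev ** 3 * P).sum(axis=(0, 1))
    prominence = (dev ** 4 * P).sum(axis=(0, 1))

    if haralick_corr == "marginal_sums":
        mu_t = px.mean(axis=0)
        var_t = px.var(axis=0)
        hcorr = np.where(var_t > _EPS, (sum_ij_p - mu_t ** 2)
                         / np.where(var_t > _EPS, var_t, 1.0), 0.0)
    elif haralick_corr == "f3":
        hcorr = correlation
    else:
        raise ValueError(f"unknown haralick_corr convention {haralick_corr!r}")

    images = {
        "energy": energy, "entropy": entropy, "correlation": correlation,
        "inverse_difference_moment": idm, "inertia": inertia,
        "cluster_shade": shade, "cluster_prominence": prominence,
        "haralick_correlation": hcorr,
    }
    out: dict[str, RasterGrid] = {}
    for name, img in images.items():
        img = np.where(valid, img, np.nan)
        out[name] = raster.copy_with(img)
    return out


def plot_texture_means(features: dict[str, RasterGrid], polygon: Polygon,
                       excluded_strip_m: float = 0.0,
                       layer: str = "") -> TextureVector:
    """Per-feature mean over valid in-polygon texture pixels."""
    means = {name: zonal_mean(features[name], polygon, excluded_strip_m)
             for name in FEATURE_NAMES}
    return TextureVector(layer=layer, **means)
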