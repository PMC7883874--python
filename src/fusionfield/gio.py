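"""File-format boundary: GeoTIFF rasters, XYZ point clouds, GeoJSON polygons.

GeoTIFFs are written through :mod:`tifffile` with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory and
GDAL_NODATA), so the outputs open in QGIS/GDAL.  Point clouds use a
whitespace-separated XYZ text format with a comment header — the portable
interchange representation for TLS exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .core import PointCloud, RasterGrid

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# ModelTypeProjected / RasterPixelIsArea
_GEO_KEYS = (1, 1, 0, 2, 1024, 0, 1, 1, 1025, 0, 1, 1)


def write_geotiff(grid: RasterGrid, path: str | Path, *,
                  dtype: str = "float32", nodata: float = -9999.0,
                  scale_factor: float | None = None) -> Path:
    """Write a single-band GeoTIFF.

    ``dtype="uint16"`` exports ``round(value * scale_factor)`` with the scale
    recorded in the image description (the convention for reflectance
    products); ``float32`` writes values as-is with NaN mapped to ``nodata``.
    """
    path = Path(path)
    vals = grid.values[::-1]  # TIFF rows run north->south
    if dtype == "uint16":
        scale = 10000.0 if scale_factor is None else scale_factor
        nodata_int = 65535
        out = np.where(np.isfinite(vals), np.round(vals * scale), nodata_int)
        out = np.clip(out, 0, 65535).astype(np.uint16)
        desc = {"scale_factor": scale, "nodata": nodata_int}
        nodata_repr = str(nodata_int)
    elif dtype == "float32":
        out = np.where(np.isfinite(vals), vals, nodata).astype(np.float32)
        desc = {"scale_factor": None, "nodata": nodata}
        nodata_repr = repr(float(nodata))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")

    y_top = grid.y0 + grid.n_rows * grid.cell_size
    c = grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, y_top, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, nodata_repr + "\x00"),
    ]
    desc["crs"] = grid.crs
    tifffile.imwrite(path, out, description=json.dumps(desc), extratags=extratags)
    return path


def read_geotiff(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF carrying pixel-scale + tiepoint tags)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = page.tags[_TAG_MODEL_TIEPOINT].value
        desc = {}
        if page.tags.get("ImageDescription") is not None:
            try:
                desc = json.loads(page.tags["ImageDescription"].value)
            except (json.JSONDecodeError, TypeError):
                desc = {}
    c = float(scale[0])
    x0 = float(tiepoint[3])
    y_top = float(tiepoint[4])
    nodata = desc.get("nodata", -9999.0)
    scale_factor = desc.get("scale_factor")
    vals = np.where(vals == nodata, np.nan, vals)
    if scale_factor:
        vals = vals / float(scale_factor)
    vals = vals[::-1]  # back to row 0 = south
    y0 = y_top - vals.shape[0] * c
    return RasterGrid(x0, y0, c, vals, crs=desc.get("crs", "local"))


def write_xyz(cloud: PointCloud, path: str | Path) -> Path:
    """Whitespace XYZ text; classification (2 = ground) as a fourth column."""
    path = Path(path)
    cols = [cloud.x, cloud.y, cloud.z]
    header = "x y z"
    if cloud.classification is not None:
        cols.append(cloud.classification.astype(float))
        header += " classification"
    np.savetxt(path, np.column_stack(cols), fmt="%.4f", header=header)
    return path


def read_xyz(path: str | Path) -> PointCloud:
    data = np.loadtxt(path, ndmin=2)
    cls = data[:, 3].astype(int) if data.shape[1] > 3 else None
    return PointCloud(data[:, 0], data[:, 1], data[:, 2], classification=cls)


def write_plot_polygons(polygons: dict[str, Polygon], properties: dict[str, dict],
                        path: str | Path) -> Path:
    """GeoJSON FeatureCollection keyed by plot_id."""
    features = []
    for plot_id, poly in polygons.items():
        props = {"plot_id": plot_id, **properties.get(plot_id, {})}
        features.append({"type": "Feature", "geometry": mapping(poly),
                         "properties": props})
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features},
                               indent=1))
    return path


def read_plot_polygons(path: str | Path) -> tuple[dict[str, Polygon], dict[str, dict]]:
    data = json.loads(Path(path).read_text())
    polygons: dict[str, Polygon] = {}
    properties: dict[str, dict] = {}
    for feat in data["features"]:
        props = dict(feat.get("properties", {}))
        plot_id = str(props.pop("plot_id"))
        polygons[plot_id] = shape(feat["geometry"])
        properties[plot_id] = props
    return polygons, properties
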