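"""File I/O: rasters, point tables, polygons and YAML configuration.

Rasters are stored as plain TIFFs (float32 for reflectance/depth, uint8 for
label maps) with the grid geometry, band list, stage/class metadata and the
nodata convention recorded as a JSON document in the TIFF description tag.
Nodata is NaN for float rasters and 0 for label rasters.  Points travel as
CSV (``x, y, class`` or ``x, y, depth_m``), polygons as GeoJSON or WKT, and
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import shape as geojson_shape

from .bathymetry import BathymetryModel
from .classification import GroundTruthPoints
from .rasters import DepthRaster, Grid, HabitatMap, ReflectanceScene

__all__ = [
    "write_raster",
    "read_raster",
    "write_points_csv",
    "read_points_csv",
    "write_depth_points_csv",
    "read_depth_points_csv",
    "read_polygon",
    "load_yaml",
    "dump_yaml",
    "write_model_yaml",
    "read_model_yaml",
]


def _grid_meta(grid: Grid) -> dict:
    return {
        "rows": grid.rows,
        "cols": grid.cols,
        "pixel_size": grid.pixel_size,
        "x_origin": grid.x_origin,
        "y_origin": grid.y_origin,
    }


def _grid_from_meta(d: dict) -> Grid:
    return Grid(
        rows=int(d["rows"]),
        cols=int(d["cols"]),
        pixel_size=float(d["pixel_size"]),
        x_origin=float(d["x_origin"]),
        y_origin=float(d["y_origin"]),
    )


def write_raster(path, obj) -> None:
    """Write a scene, depth raster or habitat map as a described TIFF."""
    path = Path(path)
    if isinstance(obj, ReflectanceScene):
        meta = {
            "kind": "reflectance",
            "grid": _grid_meta(obj.grid),
            "bands": list(obj.bands),
            "stage": obj.stage,
            "nodata": "nan",
        }
        data = obj.values.astype(np.float32)
        data[:, obj.mask] = np.nan
    elif isinstance(obj, DepthRaster):
        meta = {
            "kind": "depth",
            "grid": _grid_meta(obj.grid),
            "smoothed": obj.smoothed,
            "nodata": "nan",
        }
        data = obj.values.astype(np.float32)
        data[obj.mask] = np.nan
    elif isinstance(obj, HabitatMap):
        meta = {
            "kind": "habitat",
            "grid": _grid_meta(obj.grid),
            "class_table": {str(k): v for k, v in obj.class_table.items()},
            "nodata": 0,
        }
        data = obj.labels.astype(np.uint8)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")


def read_raster(path):
    """Read back a raster written by :func:`write_raster`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
        data = tif.asarray()
    try:
        meta = json.loads(desc)
        grid = _grid_from_meta(meta["grid"])
    except (TypeError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path} carries no grid metadata; not written by this package") from exc
    kind = meta.get("kind")
    if kind == "reflectance":
        data = np.asarray(data, dtype=float)
        if data.ndim == 2:
            data = data[None]
        mask = ~np.isfinite(data).all(axis=0)
        data = np.where(np.isfinite(data), data, 0.0)
        return ReflectanceScene(
            values=data, bands=tuple(meta["bands"]), grid=grid, mask=mask, stage=meta["stage"]
        )
    if kind == "depth":
        data = np.asarray(data, dtype=float)
        mask = ~np.isfinite(data)
        return DepthRaster(
            values=np.where(mask, 0.0, data),
            grid=grid,
            mask=mask,
            smoothed=bool(meta.get("smoothed", False)),
        )
    if kind == "habitat":
        table = {int(k): v for k, v in meta["class_table"].items()}
        return HabitatMap(labels=np.asarray(data, dtype=np.uint8), grid=grid, class_table=table)
    raise ValueError(f"unknown raster kind {kind!r} in {path}")


def write_points_csv(path, points: GroundTruthPoints) -> None:
    points.to_dataframe().to_csv(path, index=False)


def read_points_csv(path, role: str = "train") -> GroundTruthPoints:
    return GroundTruthPoints.from_dataframe(pd.read_csv(path), role=role)


def write_depth_points_csv(path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points), columns=["x", "y", "depth_m"]).to_csv(path, index=False)


def read_depth_points_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x", "y", "depth_m"]].to_numpy(dtype=float)


def read_polygon(path):
    """Load a polygon from a GeoJSON file or a WKT text file."""
    path = Path(path)
    text = path.read_text().strip()
    if path.suffix.lower() in (".wkt", ".txt") or text.upper().startswith(("POLYGON", "MULTIPOLYGON")):
        return shapely.from_wkt(text)
    doc = json.loads(text)
    if doc.get("type") == "FeatureCollection":
        doc = doc["features"][0]
    if doc.get("type") == "Feature":
        doc = doc["geometry"]
    return geojson_shape(doc)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_model_yaml(path, model: BathymetryModel) -> None:
    dump_yaml(path, model.to_dict())


def read_model_yaml(path) -> BathymetryModel:
    return BathymetryModel.from_dict(load_yaml(path))
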