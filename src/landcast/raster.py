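"""Raster and table I/O for scenario run directories.

Rasters are single-band, row-major, north-up TIFF files written with
``tifffile``: integer layers are int32 with −1 as nodata, continuous
layers float32 with NaN as nodata.  Cell-area metadata travels in the
TIFF description tag.  Tables are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .world import INT_NODATA


class DimensionError(ValueError):
    """Raster shape does not match the world raster."""


class SchemaError(ValueError):
    """Table is missing a required column."""


def write_raster(layer: np.ndarray, path, cell_area_km2: float | None = None) -> None:
    """Write a single-band raster; dtype decides the nodata convention."""
    path = Path(path)
    arr = np.asarray(layer)
    if arr.dtype == bool:
        arr = arr.astype(np.int32)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
        nodata = INT_NODATA
    else:
        arr = arr.astype(np.float32)
        nodata = "nan"
    meta = {"nodata": nodata}
    if cell_area_km2 is not None:
        meta["cell_area_km2"] = cell_area_km2
    tifffile.imwrite(path, arr, description=json.dumps(meta))


def read_raster(path, expect_shape=None) -> np.ndarray:
    """Read a single-band raster written by :func:`write_raster`."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise DimensionError(f"{path}: expected single-band 2-D raster, "
                             f"got ndim={arr.ndim}")
    if expect_shape is not None and arr.shape != tuple(expect_shape):
        raise DimensionError(f"{path}: shape {arr.shape} != expected "
                             f"{tuple(expect_shape)}")
    return arr


def raster_meta(path) -> dict:
    with tifffile.TiffFile(Path(path)) as tf:
        desc = tf.pages[0].description
    try:
        return json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        return {}


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df
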