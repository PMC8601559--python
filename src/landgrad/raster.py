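"""Georeferenced raster data model and I/O.

Grids live in projected map units (meters) with the origin at the
top-left corner, row-major storage, 0-based indices, and pixel-center
registration: the center of pixel (row, col) sits at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

Two on-disk formats are supported: single-band GeoTIFF (integer band
for categorical grids, float band for continuous ones, georeference in
the ModelPixelScale/ModelTiepoint tags) and the ESRI ASCII grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridGeoref",
    "CategoricalRaster",
    "ContinuousRaster",
    "PointSet",
    "georef_for_window",
    "read_categorical",
    "write_categorical",
    "read_continuous",
    "write_continuous",
    "crop_window",
    "extract_at_points",
    "read_points_csv",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_ASCII_PARAMS = 34737
_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridGeoref:
    """Placement of a regular grid in projected map coordinates.

    ``origin_x, origin_y`` give the map coordinates of the grid's
    top-left *corner*; ``cell_size`` is the square cell edge in map
    units; ``crs_label`` is an opaque tag carried through I/O.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_min(self) -> float:
        return self.origin_x

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin_y

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_size

    def rowcol(self, x, y):
        """Indices of the pixel containing (x, y); no bounds check."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def xy(self, row, col):
        """Map coordinates of pixel centers."""
        x = self.origin_x + (np.asarray(col, dtype=float) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row, dtype=float) + 0.5) * self.cell_size
        return x, y

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y > self.y_min) & (y <= self.y_max)


def georef_for_window(
    center_xy: tuple[float, float],
    window: float,
    cell_size: float,
    crs_label: str = "local",
) -> GridGeoref:
    """Georeference of a square analysis window around a city center.

    The side length in cells is ``round(window / cell_size)``: a
    50 000 m window on a 30 m grid gives 1 667 cells per side, since the
    ratio is not integral the nearest integer is used.
    """
    n = int(round(window / cell_size))
    if n < 1:
        raise ValueError("window smaller than one cell")
    cx, cy = center_xy
    half = n * cell_size / 2.0
    return GridGeoref(cx - half, cy + half, cell_size, n, n, crs_label)


@dataclass
class CategoricalRaster:
    """Integer-coded land-cover grid with georeference."""

    georef: GridGeoref
    values: np.ndarray
    nodata_code: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError("categorical raster requires an integer array")
        if self.values.shape != self.georef.shape:
            raise ValueError(
                f"array shape {self.values.shape} != georef shape {self.georef.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_code

    def class_codes(self) -> list[int]:
        """Sorted distinct non-nodata codes present in the grid."""
        vals = np.unique(self.values[self.valid_mask])
        return [int(v) for v in vals]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CategoricalRaster):
            return NotImplemented
        return (
            self.georef == other.georef
            and self.nodata_code == other.nodata_code
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ContinuousRaster:
    """Real-valued grid (e.g. a smoothed class fraction surface)."""

    georef: GridGeoref
    values: np.ndarray
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.georef.shape:
            raise ValueError(
                f"array shape {self.values.shape} != georef shape {self.georef.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        if math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


@dataclass
class PointSet:
    """Named point locations (site coordinates) in map units."""

    ids: list = field(default_factory=list)
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == self.x.size == self.y.size):
            raise ValueError("ids, x, y must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("point ids must be unique")


def read_points_csv(path) -> PointSet:
    """Read a point set from CSV with header ``id,x,y``."""
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"point CSV missing columns: {sorted(missing)}")
    return PointSet(list(df["id"]), df["x"].to_numpy(), df["y"].to_numpy())


# ---------------------------------------------------------------------------
# format detection and I/O


def _detect_format(path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower().replace("-", "_").replace(" ", "_")
        if fmt in ("geotiff", "tif", "tiff"):
            return "geotiff"
        if fmt in ("ascii", "aaigrid", "esri_ascii", "asc", "esri_ascii_grid"):
            return "ascii"
        raise ValueError(f"unknown raster format: {format!r}")
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".txt", ".grd"):
        return "ascii"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r}")


def _read_ascii(path):
    """Parse an ESRI ASCII grid header and body."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner",
            "xllcenter", "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII header: missing {key}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_ll, y_ll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        x_ll = header["xllcenter"] - cell / 2.0
        y_ll = header["yllcenter"] - cell / 2.0
    else:
        raise ValueError("malformed ESRI ASCII header: missing corner/center")
    body = "\n".join(lines[i:])
    # tokens may wrap across lines; reshape by the declared dimensions
    values = np.array(body.split(), dtype=float).reshape(n_rows, n_cols)
    georef = GridGeoref(x_ll, y_ll + n_rows * cell, cell, n_rows, n_cols)
    nodata = header.get("nodata_value", -9999.0)
    return georef, values, nodata


def _write_ascii(path, georef: GridGeoref, values: np.ndarray, nodata, fmt: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {georef.n_cols}\n")
        fh.write(f"nrows {georef.n_rows}\n")
        fh.write(f"xllcorner {georef.x_min!r}\n")
        fh.write(f"yllcorner {georef.y_min!r}\n")
        fh.write(f"cellsize {georef.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, values, fmt=fmt)


def _geotiff_extratags(georef: GridGeoref, nodata) -> list:
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (georef.cell_size, georef.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.origin_x, georef.origin_y, 0.0)),
        (_GEO_ASCII_PARAMS, "s", None, georef.crs_label),
        (_GDAL_NODATA, "s", None, str(nodata)),
    ]


def _read_geotiff(path):
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: GeoTIFF lacks georeferencing tags")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        if abs(scale[0] - scale[1]) > 1e-9 * max(scale[0], scale[1]):
            raise ValueError("non-square cells are not supported")
        # tiepoint maps raster (i, j) to world (x, y); only (0, 0) anchors used
        origin_x = tie[3] - tie[0] * scale[0]
        origin_y = tie[4] + tie[1] * scale[1]
        crs = tags[_GEO_ASCII_PARAMS].value if _GEO_ASCII_PARAMS in tags else "local"
        crs = crs.rstrip("\x00").rstrip("|")
        nodata = tags[_GDAL_NODATA].value if _GDAL_NODATA in tags else None
    if values.ndim != 2:
        raise ValueError("multi-band rasters are not supported")
    n_rows, n_cols = values.shape
    georef = GridGeoref(origin_x, origin_y, float(scale[0]), n_rows, n_cols, crs)
    return georef, values, nodata


def read_categorical(path, format: str | None = None) -> CategoricalRaster:
    """Load an integer land-cover grid from GeoTIFF or ESRI ASCII.

    Unknown class codes are preserved verbatim; nodata cells are
    carried via ``nodata_code``, never folded into a class.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "geotiff":
        georef, values, nodata = _read_geotiff(path)
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values[np.isfinite(values)] == np.round(values[np.isfinite(values)])):
                raise ValueError(f"{path}: non-integer band in categorical raster")
            values = values.astype(np.int64)
        nodata_code = int(float(nodata)) if nodata is not None else -9999
        return CategoricalRaster(georef, values.astype(np.int64), nodata_code)
    georef, values, nodata = _read_ascii(path)
    if not np.all(values == np.round(values)):
        raise ValueError(f"{path}: non-integer values in categorical ASCII grid")
    return CategoricalRaster(georef, values.astype(np.int64), int(nodata))


def write_categorical(raster: CategoricalRaster, path, format: str | None = None) -> None:
    fmt = _detect_format(path, format)
    if fmt == "geotiff":
        tifffile.imwrite(
            path,
            raster.values.astype(np.int32),
            extratags=_geotiff_extratags(raster.georef, raster.nodata_code),
        )
    else:
        _write_ascii(path, raster.georef, raster.values, raster.nodata_code, fmt="%d")


def read_continuous(path, format: str | None = None) -> ContinuousRaster:
    """Load a float grid from GeoTIFF or ESRI ASCII."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "geotiff":
        georef, values, nodata = _read_geotiff(path)
        nod = float(nodata) if nodata is not None else float("nan")
        return ContinuousRaster(georef, values.astype(float), nod)
    georef, values, nodata = _read_ascii(path)
    out = values.astype(float)
    out[out == nodata] = np.nan
    return ContinuousRaster(georef, out, float("nan"))


def write_continuous(raster: ContinuousRaster, path, format: str | None = None) -> None:
    fmt = _detect_format(path, format)
    if fmt == "geotiff":
        tifffile.imwrite(
            path,
            raster.values.astype(np.float64),
            extratags=_geotiff_extratags(raster.georef, raster.nodata),
        )
    else:
        vals = raster.values.copy()
        vals[~raster.valid_mask] = -9999.0
        _write_ascii(path, raster.georef, vals, -9999.0, fmt="%.10g")


# ---------------------------------------------------------------------------
# spatial operations


def crop_window(raster: CategoricalRaster, center_xy: tuple[float, float], half_width: float) -> CategoricalRaster:
    """Crop a square window of ±half_width around a center point.

    Cells of the window falling outside the source raster become
    nodata, so windows may straddle the raster edge.
    """
    g = raster.georef
    cx, cy = center_xy
    n = int(round(2 * half_width / g.cell_size))
    n = max(n, 1)
    # top-left corner of the window snapped to the source grid
    row0 = int(round((g.origin_y - (cy + half_width)) / g.cell_size))
    col0 = int(round(((cx - half_width) - g.origin_x) / g.cell_size))
    if row0 >= g.n_rows or col0 >= g.n_cols or row0 + n <= 0 or col0 + n <= 0:
        raise ValueError("crop window does not intersect the raster")
    out = np.full((n, n), raster.nodata_code, dtype=raster.values.dtype)
    src_r0, src_r1 = max(row0, 0), min(row0 + n, g.n_rows)
    src_c0, src_c1 = max(col0, 0), min(col0 + n, g.n_cols)
    out[src_r0 - row0 : src_r1 - row0, src_c0 - col0 : src_c1 - col0] = raster.values[
        src_r0:src_r1, src_c0:src_c1
    ]
    georef = GridGeoref(
        g.origin_x + col0 * g.cell_size,
        g.origin_y - row0 * g.cell_size,
        g.cell_size,
        n,
        n,
        g.crs_label,
    )
    return CategoricalRaster(georef, out, raster.nodata_code)


def extract_at_points(raster, points: PointSet) -> pd.DataFrame:
    """Nearest-pixel-center lookup of raster values at point locations.

    Returns a frame with columns ``id, value, inside``; points outside
    the extent are flagged (``inside=False``, value missing) rather
    than dropped. Nodata cells propagate as missing values.
    """
    g = raster.georef
    inside = g.contains(points.x, points.y)
    row, col = g.rowcol(points.x, points.y)
    row = np.clip(row, 0, g.n_rows - 1)
    col = np.clip(col, 0, g.n_cols - 1)
    raw = raster.values[row, col].astype(float)
    if isinstance(raster, CategoricalRaster):
        valid = raster.values[row, col] != raster.nodata_code
    else:
        valid = raster.valid_mask[row, col]
    value = np.where(inside & valid, raw, np.nan)
    return pd.DataFrame({"id": points.ids, "value": value, "inside": inside})
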