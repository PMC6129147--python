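"""Georeferenced containers and I/O: rasters, occurrence tables, station series.

Conventions
-----------
* Coordinates are WGS84 decimal degrees.
* A :class:`RasterGrid` is row-major with row 0 at the *northern* edge;
  ``x_origin``/``y_origin`` are the coordinates of the lower-left (south-west)
  corner of the grid, matching the ESRI ASCII ``xllcorner``/``yllcorner``
  convention. Registration is cell-centre; a point belongs to the half-open
  cell ``[x, x + cell_size) x [y, y + cell_size)``.
* Rasters are read and written as ESRI ASCII grids (bit-exact round trip) or
  GeoTIFF (float32, ModelPixelScale/ModelTiepoint/GDAL_NODATA tags).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError, GridFormatError, SchemaError

logger = logging.getLogger(__name__)

ASCII_NODATA = -9999.0


# ---------------------------------------------------------------------------
# Raster containers
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A georeferenced 2D grid of real values with a no-data mask.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values; entries under the mask are ignored (stored as NaN).
    nodata_mask : ndarray of bool, same shape
        True where the cell carries no data.
    x_origin, y_origin : float
        Lower-left corner, decimal degrees.
    cell_size : float
        Cell edge length in degrees; must be positive.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        bad = ~np.isfinite(self.values) & ~self.nodata_mask
        if bad.any():
            raise ValueError("values must be finite wherever nodata_mask is false")
        self.values = self.values.copy()
        self.values[self.nodata_mask] = np.nan

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of every cell centre, each shaped (n_rows, n_cols)."""
        cs = self.cell_size
        lon = self.x_origin + (np.arange(self.n_cols) + 0.5) * cs
        lat = self.y_origin + (self.n_rows - np.arange(self.n_rows) - 0.5) * cs
        return np.meshgrid(lon, lat)

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the half-open cell containing each point, plus in-bounds flag."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(int)
        row_from_s = np.floor((lat - self.y_origin) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_s
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            values=values,
            nodata_mask=self.nodata_mask.copy() if mask is None else mask,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
        )


@dataclass
class ClimateStack:
    """Named, co-registered raster layers (e.g. ``bio7`` ... ``bio16``)."""

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("ClimateStack needs at least one layer")
        names = list(self.layers)
        ref = self.layers[names[0]]
        for name in names[1:]:
            g = self.layers[name]
            if not ref.same_geometry(g):
                raise GeometryError(f"layer {name!r} geometry differs from {names[0]!r}")
            if not np.array_equal(ref.nodata_mask, g.nodata_mask):
                raise GeometryError(f"layer {name!r} nodata mask differs from {names[0]!r}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def geometry(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return ClimateStack({n: self.layers[n] for n in names})


# ---------------------------------------------------------------------------
# Occurrences and stations
# ---------------------------------------------------------------------------

OCC_COLUMNS = ["longitude", "latitude", "year", "presence", "weight"]


@dataclass
class OccurrenceTable:
    """Pest occurrence records: (longitude, latitude, year, presence, weight)."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=OCC_COLUMNS))

    def __post_init__(self) -> None:
        df = self.records.copy()
        if "presence" not in df.columns:
            df["presence"] = 1
        if "weight" not in df.columns:
            df["weight"] = 1.0
        missing = [c for c in ("longitude", "latitude", "year") if c not in df.columns]
        if missing:
            raise SchemaError(f"occurrence table missing columns: {missing}")
        df = df[OCC_COLUMNS].reset_index(drop=True)
        if len(df):
            if not ((df.longitude.between(-180, 180)) & (df.latitude.between(-90, 90))).all():
                raise ValueError("coordinates outside valid lon/lat ranges")
            if (df.weight <= 0).any():
                raise ValueError("weights must be positive")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records.longitude.to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.records.latitude.to_numpy(float)

    def filter_years(self, years: Iterable[int]) -> "OccurrenceTable":
        years = set(int(y) for y in years)
        return OccurrenceTable(self.records[self.records.year.isin(years)])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class StationSeries:
    """Daily weather series at one station."""

    station_id: str
    longitude: float
    latitude: float
    data: pd.DataFrame  # date, mean_temp, min_temp, max_temp, dew_point, wind_speed, precipitation

    DAILY_COLUMNS = (
        "date", "mean_temp", "min_temp", "max_temp", "dew_point", "wind_speed", "precipitation",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.DAILY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"station series missing columns: {missing}")
        d = self.data
        if len(d):
            ok = (d.min_temp <= d.mean_temp + 1e-9) & (d.mean_temp <= d.max_temp + 1e-9)
            if not ok.all():
                raise ValueError("min_temp <= mean_temp <= max_temp violated")

    def annual_means(self, year: int) -> dict[str, float] | None:
        """Mean of each daily factor over the given calendar year; None if no data."""
        d = self.data
        if not len(d):
            return None
        yrs = pd.to_datetime(d.date).dt.year
        sub = d[yrs == year]
        if not len(sub):
            return None
        return {
            c: float(sub[c].mean())
            for c in self.DAILY_COLUMNS
            if c != "date"
        }


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("ascii-grid", "geotiff"):
            raise ConfigurationError(f"unknown raster dialect {dialect!r}")
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    return "ascii-grid"


def read_raster(path, dialect: str | None = None) -> RasterGrid:
    """Read a raster from disk (ESRI ASCII grid or GeoTIFF)."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "ascii-grid":
        return _read_ascii_grid(path)
    return _read_geotiff(path)


def write_raster(grid: RasterGrid, path, dialect: str | None = None) -> None:
    """Write a raster to disk; round-trips bit-exactly for ASCII grids."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "ascii-grid":
        _write_ascii_grid(grid, path)
    else:
        _write_geotiff(grid, path)


_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path) -> RasterGrid:
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            try:
                header[m.group(1).lower()] = float(m.group(2))
            except ValueError as e:
                raise GridFormatError(f"unparseable header value for {m.group(1)!r}: {m.group(2)!r}") from e
            body_start = i + 1
        else:
            break
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"ASCII grid header missing required field {key!r}")
    nodata = header.get("nodata_value", ASCII_NODATA)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        data = np.array(
            [float(tok) for line in lines[body_start:] for tok in line.split()],
            dtype=float,
        )
    except ValueError as e:
        raise GridFormatError(f"unparseable cell value in grid body: {e}") from e
    if data.size != n_rows * n_cols:
        raise GridFormatError(
            f"grid body has {data.size} values, expected nrows*ncols = {n_rows * n_cols}"
        )
    values = data.reshape(n_rows, n_cols)
    mask = values == nodata
    return RasterGrid(
        values=np.where(mask, np.nan, values),
        nodata_mask=mask,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
    )


def _write_ascii_grid(grid: RasterGrid, path) -> None:
    out = np.where(grid.nodata_mask, ASCII_NODATA, grid.values)
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.x_origin!r}",
        f"yllcorner {grid.y_origin!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {ASCII_NODATA!r}",
    ]
    lines += [" ".join(repr(float(v)) for v in row) for row in out]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_geotiff(path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        tags = {t.name: t.value for t in page.tags.values()}
        if "ModelPixelScaleTag" not in tags or "ModelTiepointTag" not in tags:
            raise GridFormatError("GeoTIFF missing ModelPixelScaleTag/ModelTiepointTag")
        sx, sy = tags["ModelPixelScaleTag"][:2]
        if abs(sx - sy) > 1e-12:
            raise GridFormatError("GeoTIFF has non-square pixels (ModelPixelScaleTag)")
        i, j, _, x, y, _ = tags["ModelTiepointTag"][:6]
        if i != 0 or j != 0:
            raise GridFormatError("GeoTIFF tie point must anchor the (0,0) pixel corner")
        values = page.asarray().astype(float)
        nodata_tag = tags.get("GDAL_NODATA")
    mask = ~np.isfinite(values)
    if nodata_tag is not None:
        try:
            nd = float(nodata_tag)
            mask |= values == nd
        except ValueError:
            pass
    n_rows = values.shape[0]
    return RasterGrid(
        values=np.where(mask, np.nan, values),
        nodata_mask=mask,
        x_origin=float(x),
        y_origin=float(y) - n_rows * float(sx),
        cell_size=float(sx),
    )


def _write_geotiff(grid: RasterGrid, path) -> None:
    import tifffile

    cs = grid.cell_size
    north = grid.y_origin + grid.n_rows * cs
    out = np.where(grid.nodata_mask, np.nan, grid.values).astype(np.float32)
    tifffile.imwrite(
        path,
        out,
        extratags=[
            (33550, "d", 3, (cs, cs, 0.0)),       # ModelPixelScaleTag
            (33922, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, north, 0.0)),  # ModelTiepointTag
            (42113, "s", 0, "nan"),               # GDAL_NODATA
        ],
    )


def read_stack(paths: dict[str, str], dialect: str | None = None) -> ClimateStack:
    """Read a named set of co-registered rasters into a stack."""
    return ClimateStack({name: read_raster(p, dialect) for name, p in paths.items()})


def write_stack(stack: ClimateStack, directory, dialect: str = "ascii-grid") -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if dialect == "ascii-grid" else ".tif"
    out = {}
    for name, grid in stack.layers.items():
        p = directory / f"{name}{ext}"
        write_raster(grid, p, dialect)
        out[name] = p
    return out


# ---------------------------------------------------------------------------
# Occurrence I/O and the geographic calibration split
# ---------------------------------------------------------------------------

def read_occurrences(path) -> OccurrenceTable:
    """Read occurrence records from CSV.

    Requires ``longitude``, ``latitude`` and ``year`` columns; ``presence``
    (default 1) and ``weight`` (default 1) are optional. Rows whose
    coordinates cannot be parsed or fall outside valid lon/lat ranges are
    dropped with a logged count.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("longitude", "latitude", "year") if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence CSV {path} missing required columns: {missing}")
    n_raw = len(df)
    for c in ("longitude", "latitude", "year"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    valid = (
        df.longitude.between(-180, 180)
        & df.latitude.between(-90, 90)
        & df.year.notna()
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("read_occurrences: dropped %d of %d rows with invalid coordinates/year", n_dropped, n_raw)
    df = df[valid].copy()
    df["year"] = df.year.astype(int)
    return OccurrenceTable(df)


Band = tuple[float, float]


def _check_bands(train_band: Band, test_bands: Sequence[Band]) -> None:
    all_bands = [tuple(train_band)] + [tuple(b) for b in test_bands]
    for lo, hi in all_bands:
        if not lo < hi:
            raise ConfigurationError(f"degenerate longitude band [{lo}, {hi}]")
    for i in range(len(all_bands)):
        for j in range(i + 1, len(all_bands)):
            a, b = all_bands[i], all_bands[j]
            if a[0] < b[1] and b[0] < a[1]:
                raise ConfigurationError(f"overlapping longitude bands {a} and {b}")


def split_by_longitude(
    table: OccurrenceTable,
    train_band: Band,
    test_bands: Sequence[Band],
) -> tuple[OccurrenceTable, OccurrenceTable]:
    """Geographic calibration/validation split by longitude bands.

    Each band is the half-open interval ``[lon_min, lon_max)`` (a record at
    exactly the lower edge of the training band goes to training). Records in
    no band are excluded from both outputs.
    """
    _check_bands(train_band, test_bands)
    lon = table.lon
    in_train = (lon >= train_band[0]) & (lon < train_band[1])
    in_test = np.zeros_like(in_train)
    for lo, hi in test_bands:
        in_test |= (lon >= lo) & (lon < hi)
    train = OccurrenceTable(table.records[in_train])
    test = OccurrenceTable(table.records[in_test])
    return train, test


def holdout_split(
    table: OccurrenceTable, test_fraction: float = 0.25, seed: int = 0
) -> tuple[OccurrenceTable, OccurrenceTable]:
    """Random train/test record split (fallback when a geographic split
    leaves the validation bands empty)."""
    if not 0 < test_fraction < 1:
        raise ConfigurationError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_test = max(int(round(n * test_fraction)), 1)
    idx = rng.permutation(n)
    test_idx = np.zeros(n, dtype=bool)
    test_idx[idx[:n_test]] = True
    return (OccurrenceTable(table.records[~test_idx]),
            OccurrenceTable(table.records[test_idx]))


def extract_at(stack: ClimateStack, points: Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Sample every stack layer at the given (lon, lat) points.

    Returns a DataFrame with one column per layer plus boolean ``in_bounds``
    and ``masked`` flags; out-of-bounds or masked points carry NaN values
    rather than raising.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    geom = stack.geometry
    row, col, inside = geom.index_of(pts[:, 0], pts[:, 1])
    r = np.where(inside, row, 0)
    c = np.where(inside, col, 0)
    out = {}
    masked = np.zeros(len(pts), dtype=bool)
    for name, grid in stack.layers.items():
        vals = grid.values[r, c]
        vals = np.where(inside, vals, np.nan)
        out[name] = vals
        masked |= inside & grid.nodata_mask[r, c]
    df = pd.DataFrame(out)
    df["in_bounds"] = inside
    df["masked"] = masked
    return df
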