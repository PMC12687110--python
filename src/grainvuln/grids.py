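"""Regular-lattice environmental grids.

A :class:`Grid` is one environmental variable (temperature in °C or
precipitation in mm) on a square lattice in a planar km coordinate system.
The array convention used throughout the package is *row 0 = southernmost
row*: the center of cell ``(r, c)`` sits at
``(x0 + (c + 0.5) * cell_size, y0 + (r + 0.5) * cell_size)`` where
``(x0, y0)`` is the lower-left corner of the lattice.  x increases east,
y increases north.  Distances between cells are Euclidean on the km plane;
great-circle geometry is out of scope for this synthetic planar world.

The module provides block aggregation across a grain-size ladder (the mean
of each ``factor`` × ``factor`` block of fine cells), the distance-band
Moran's I autocorrelation coefficient, and IO for single-band GeoTIFF and
ESRI ASCII grid files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, GridParseError, InvalidArgumentError

__all__ = [
    "Grid",
    "MonthlyStack",
    "PeriodMean",
    "aggregate",
    "morans_i",
    "read_grid",
    "write_grid",
]

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """One variable on a regular square lattice.

    Parameters
    ----------
    values : (nrows, ncols) float array
        Cell values; entries under ``missing_mask`` are ignored everywhere
        and set to NaN on construction.
    cell_size : float
        Cell edge length in km; must be positive.
    origin : (float, float)
        ``(x0, y0)`` of the lower-left corner, km.
    missing_mask : (nrows, ncols) bool array, optional
        True where the cell has no data.  Defaults to ``isnan(values)``.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise InvalidArgumentError(f"cell_size must be > 0, got {self.cell_size}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise InvalidArgumentError(
                    "missing_mask shape differs from values shape"
                )
            self.missing_mask = self.missing_mask | np.isnan(self.values)
        self.values = np.where(self.missing_mask, np.nan, self.values)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` center coordinate arrays, each (nrows, ncols)."""
        nr, nc = self.shape
        x = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) by half-open cell membership.

        A point belongs to cell ``(r, c)`` iff
        ``x ∈ [x0 + c·s, x0 + (c+1)·s)`` and likewise for y, which makes
        boundary assignment deterministic.  Indices may fall outside the
        lattice; callers check bounds.
        """
        c = np.floor((np.asarray(x, dtype=float) - self.origin[0]) / self.cell_size)
        r = np.floor((np.asarray(y, dtype=float) - self.origin[1]) / self.cell_size)
        return r.astype(np.int64), c.astype(np.int64)

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


@dataclass
class MonthlyStack:
    """One monthly layer of one variable: (variable, year, month) → grid."""

    variable: str
    year: int
    month: int
    grid: Grid

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise InvalidArgumentError(f"month must be in 1..12, got {self.month}")


@dataclass
class PeriodMean:
    """A period-averaged layer: the recent (t0) or future (t1) condition."""

    variable: str
    period: str  # "recent_t0" or "future_t1"
    grid: Grid


def aggregate(grid: Grid, factor: int) -> Grid:
    """Aggregate a grid to a coarser grain by block averaging.

    Each output cell is the arithmetic mean of the non-missing input cells in
    its ``factor`` × ``factor`` block; the output cell is missing iff every
    input cell in the block is missing.  Trailing partial blocks (when the
    dimensions are not divisible by ``factor``) average the available cells,
    matching standard raster aggregation semantics.  The origin is preserved
    and the output ``cell_size`` is ``factor`` times the input one.
    """
    if int(factor) != factor or factor <= 0:
        raise InvalidArgumentError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return Grid(grid.values.copy(), grid.cell_size, grid.origin, grid.missing_mask.copy())
    nr, nc = grid.shape
    out_r = math.ceil(nr / factor)
    out_c = math.ceil(nc / factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = grid.values
    blocks = padded.reshape(out_r, factor, out_c, factor)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(blocks), axis=(1, 3))
        sums = np.nansum(blocks, axis=(1, 3))
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Grid(out, grid.cell_size * factor, grid.origin, counts == 0)


def morans_i(grid: Grid, max_distance: float, mask: np.ndarray | None = None) -> float:
    """Moran's I with binary distance-band weights.

    Weights are ``w_ij = 1`` for distinct cells whose centers are within
    ``max_distance`` km (Euclidean), else 0 — no row standardization.  The
    statistic is computed over non-missing cells, optionally restricted to
    ``mask`` (True = include)::

        I = (N / Σw) · (Σ_ij w_ij z_i z_j) / (Σ_i z_i²),   z = value − mean.

    Raises :class:`DegenerateInputError` on zero variance or when no pair of
    included cells lies within the band.
    """
    include = ~grid.missing_mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise InvalidArgumentError("mask shape differs from grid shape")
        include = include & mask
    vals = grid.values[include]
    n = vals.size
    if n < 2:
        raise DegenerateInputError(f"need ≥ 2 included cells, got {n}")
    z = vals - vals.mean()
    ss = float(z @ z)
    if ss == 0.0:
        raise DegenerateInputError("zero variance among included cells")
    xx, yy = grid.cell_centers()
    pts = np.column_stack([xx[include], yy[include]])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=max_distance, output_type="ndarray")
    if len(pairs) == 0:
        raise DegenerateInputError(
            f"no pair of included cells within {max_distance} km"
        )
    cross = float(np.sum(z[pairs[:, 0]] * z[pairs[:, 1]]))
    w_sum = 2.0 * len(pairs)  # each unordered pair counts twice in Σ_ij
    return (n / w_sum) * (2.0 * cross) / ss


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write a grid as single-band GeoTIFF or ESRI ASCII grid.

    The format is inferred from the suffix (``.tif``/``.tiff`` vs ``.asc``)
    unless given explicitly.  Missing cells are stored via the format's
    nodata convention.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise InvalidArgumentError(f"unknown grid format {fmt!r}")


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a grid written by :func:`write_grid` (or any conforming file)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise InvalidArgumentError(f"unknown grid format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    if suffix in {".asc", ".agr", ".grd"}:
        return "ascii_grid"
    raise InvalidArgumentError(f"cannot infer grid format from suffix {suffix!r}")


def _write_ascii(grid: Grid, path: Path) -> None:
    nr, nc = grid.shape
    vals = np.where(grid.missing_mask, _DEFAULT_NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {grid.origin[1]!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {_DEFAULT_NODATA!r}\n")
        # ESRI ASCII rows run north → south; our row 0 is the southernmost.
        for row in vals[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(rows) == 0 and key in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                try:
                    header[key] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise GridParseError(
                        f"{path}:{lineno}: bad header line {line!r}"
                    ) from exc
            else:
                try:
                    rows.append(np.array([float(p) for p in parts]))
                except ValueError as exc:
                    raise GridParseError(
                        f"{path}:{lineno}: non-numeric data {line!r}"
                    ) from exc
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise GridParseError(f"{path}: missing header field {req!r}")
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if len(rows) != nr or any(r.size != nc for r in rows):
        raise GridParseError(
            f"{path}: data block is not {nr} rows × {nc} cols"
        )
    data = np.vstack(rows)[::-1]  # back to south-first row order
    nodata = header.get("nodata_value")
    missing = np.isnan(data)
    if nodata is not None:
        missing |= data == nodata
    return Grid(
        np.where(missing, np.nan, data),
        header["cellsize"],
        (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        missing,
    )


# GeoTIFF tag ids: pixel scale, tiepoint, GDAL nodata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    nr, nc = grid.shape
    s = grid.cell_size
    # TIFF raster rows run top → bottom; tiepoint anchors raster (0,0) at the
    # upper-left map corner.
    y_top = grid.origin[1] + nr * s
    data = np.where(grid.missing_mask, _DEFAULT_NODATA, grid.values)[::-1]
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(_DEFAULT_NODATA)),
    ]
    tifffile.imwrite(path, data.astype(np.float64), extratags=extratags)


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(np.float64)
            tags = {tag.code: tag.value for tag in page.tags.values()}
    except Exception as exc:  # malformed container
        raise GridParseError(f"{path}: not a readable TIFF file: {exc}") from exc
    if data.ndim != 2:
        raise GridParseError(f"{path}: expected a single-band raster")
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tie = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is None or tie is None:
        raise GridParseError(f"{path}: missing GeoTIFF georeferencing tags")
    s = float(scale[0])
    x0 = float(tie[3])
    y_top = float(tie[4])
    nr = data.shape[0]
    origin = (x0, y_top - nr * s)
    nodata_tag = tags.get(_TAG_GDAL_NODATA)
    missing = np.isnan(data)
    if nodata_tag is not None:
        try:
            missing |= data == float(nodata_tag)
        except ValueError as exc:
            raise GridParseError(f"{path}: bad GDAL nodata tag {nodata_tag!r}") from exc
    return Grid(np.where(missing, np.nan, data)[::-1], s, origin, missing[::-1])
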