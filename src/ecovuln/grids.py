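"""Raster data model and I/O.

A :class:`Grid` is one single-band raster: a 2-D value array, a boolean
validity mask, a square cell size in metres and the map coordinates of the
upper-left corner.  Row 0 is the northernmost row; cell ``(r, c)`` covers the
half-open square ``[x, x + cell) x (y - cell, y]`` where ``x, y`` are the
cell's upper-left corner coordinates.  The in-memory mask is authoritative:
whatever nodata sentinel a file declares, invalid cells are excluded from
every statistic downstream.

Supported on-disk dialects are ESRI ASCII grid (``.asc``) and single-band
GeoTIFF (via :mod:`tifffile`, using the ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags).  Zone polygons are accepted as GeoJSON and rasterized onto
a reference geometry with a cell-center-in-polygon rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Grid",
    "IndicatorMeta",
    "IndicatorStack",
    "ZoneMap",
    "GridFormatError",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "assert_aligned",
    "class_areas",
    "load_zones_geojson",
]

DEFAULT_CELL_SIZE = 30.0  # metres


class GridFormatError(ValueError):
    """A raster file could not be parsed in the requested dialect."""


class AlignmentError(ValueError):
    """Layers of a stack do not share shape, cell size, or origin."""


@dataclass
class Grid:
    """One raster band with geometry and a validity mask.

    Parameters
    ----------
    values:
        2-D array of cell values (float measurements or integer category
        codes).
    mask:
        Boolean array of the same shape; ``True`` marks a valid cell.
        ``None`` means every cell is valid.
    cell_size:
        Square cell edge length in metres (default 30).
    origin:
        ``(x, y)`` map coordinates of the upper-left corner of cell (0, 0).
    crs_tag:
        Opaque CRS string carried through I/O, never interpreted.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    cell_size: float = DEFAULT_CELL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("values and mask shapes differ")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic accessors ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        """Flat array of the values at valid cells."""
        return self.values[self.mask]

    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates ``(x, y)`` of every cell center, as 2-D arrays."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        xs = x0 + (cols + 0.5) * self.cell_size
        ys = y0 - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New Grid sharing this geometry with different values."""
        return Grid(
            values=np.asarray(values),
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            cell_size=self.cell_size,
            origin=self.origin,
            crs_tag=self.crs_tag,
        )

    def copy(self) -> "Grid":
        return self.with_values(self.values.copy(), self.mask.copy())

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol * max(1.0, abs(self.origin[0]))
            and abs(self.origin[1] - other.origin[1]) <= tol * max(1.0, abs(self.origin[1]))
        )


@dataclass(frozen=True)
class IndicatorMeta:
    """Per-indicator metadata: polarity and semantic units."""

    polarity: str  # "positive" | "negative" | "categorical"
    units: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative", "categorical"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class IndicatorStack:
    """Named, aligned single-band rasters for one epoch.

    ``layers`` preserves insertion order; indicator names are unique by
    construction of the mapping.  The common mask is the intersection of all
    layer masks — multi-layer statistics only ever see cells valid in every
    layer.
    """

    epoch: str
    layers: dict[str, Grid] = field(default_factory=dict)
    meta: dict[str, IndicatorMeta] = field(default_factory=dict)

    def __iter__(self) -> Iterator[tuple[str, Grid]]:
        return iter(self.layers.items())

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def add(self, name: str, grid: Grid, meta: IndicatorMeta | None = None) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate indicator name {name!r}")
        self.layers[name] = grid
        if meta is not None:
            self.meta[name] = meta

    def common_mask(self) -> np.ndarray:
        """Intersection of all layer masks."""
        if not self.layers:
            raise ValueError("empty stack has no mask")
        mask = None
        for g in self.layers.values():
            mask = g.mask.copy() if mask is None else (mask & g.mask)
        return mask

    def reference(self) -> Grid:
        """First layer, used as the geometry template."""
        return next(iter(self.layers.values()))


@dataclass
class ZoneMap:
    """Integer zone codes on a grid plus human-readable names."""

    zones: Grid
    names: dict[int, str]

    def __post_init__(self) -> None:
        present = set(np.unique(self.zones.values[self.zones.mask]).astype(int).tolist())
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"zone codes without names: {sorted(missing)}")

    def codes(self) -> list[int]:
        return sorted(set(np.unique(self.zones.values[self.zones.mask]).astype(int).tolist()))


# ----------------------------------------------------------------------------
# ESRI ASCII grid
# ----------------------------------------------------------------------------

def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value") and len(parts) == 2:
                    header[key] = float(parts[1])
                else:
                    rows.append([float(p) for p in parts])
    except (OSError, ValueError) as exc:
        raise GridFormatError(f"cannot parse {path} as ESRI ASCII grid: {exc}") from exc

    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise GridFormatError(f"{path}: missing header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array([v for row in rows for v in row], dtype=float)
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} cells, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    if "nodata_value" in header:
        nodata = header["nodata_value"]
        mask = values != nodata
    else:
        warnings.warn(f"{path}: no NODATA_value declared; all cells treated as valid")
        mask = np.ones_like(values, dtype=bool)
    cell = header["cellsize"]
    # ASCII grids give the lower-left corner; our origin is the upper-left.
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Grid(values=values, mask=mask, cell_size=cell, origin=origin)


def _write_ascii(grid: Grid, path: Path, nodata: float = -9999.0) -> None:
    nrows, ncols = grid.shape
    vals = np.array(grid.values, dtype=float, copy=True)
    vals[~grid.mask] = nodata
    x0, y_ul = grid.origin
    yll = y_ul - nrows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ----------------------------------------------------------------------------
# GeoTIFF (tifffile)
# ----------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550   # ModelPixelScaleTag
_TAG_TIEPOINT = 33922      # ModelTiepointTag
_TAG_GDAL_NODATA = 42113   # GDAL_NODATA (ascii)


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            # tag values are lazy; materialize them while the file is open
            tag_values = {code: page.tags[code].value
                          for code in (_TAG_PIXEL_SCALE, _TAG_TIEPOINT,
                                       _TAG_GDAL_NODATA, 270)
                          if code in page.tags}
    except Exception as exc:  # tifffile raises several exception types
        raise GridFormatError(f"cannot parse {path} as GeoTIFF: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster")

    cell = DEFAULT_CELL_SIZE
    if _TAG_PIXEL_SCALE in tag_values:
        cell = float(tag_values[_TAG_PIXEL_SCALE][0])
    origin = (0.0, 0.0)
    if _TAG_TIEPOINT in tag_values:
        tie = tag_values[_TAG_TIEPOINT]
        # (i, j, k, x, y, z): raster point (i, j) pins to map point (x, y)
        origin = (float(tie[3]) - float(tie[0]) * cell,
                  float(tie[4]) + float(tie[1]) * cell)
    values = np.asarray(values, dtype=float)
    if _TAG_GDAL_NODATA in tag_values:
        nodata = float(str(tag_values[_TAG_GDAL_NODATA]))
        mask = ~(np.isclose(values, nodata) | np.isnan(values))
    else:
        warnings.warn(f"{path}: no nodata declared; all cells treated as valid")
        mask = ~np.isnan(values)
    # ImageDescription carries the crs_tag through I/O
    crs_tag = str(tag_values.get(270, ""))
    return Grid(values=values, mask=mask, cell_size=cell, origin=origin, crs_tag=crs_tag)


def _write_geotiff(grid: Grid, path: Path, nodata: float = -9999.0) -> None:
    import tifffile

    vals = np.array(grid.values, dtype=np.float64, copy=True)
    vals[~grid.mask] = nodata
    x0, y0 = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata:.10g}"),
    ]
    tifffile.imwrite(
        path,
        vals,
        extratags=extratags,
        description=grid.crs_tag or None,
    )


# ----------------------------------------------------------------------------
# Public I/O
# ----------------------------------------------------------------------------

_FORMATS = {"geotiff", "ascii-grid"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".grd", ".txt"):
        return "ascii-grid"
    raise GridFormatError(f"cannot infer raster dialect from {path.name!r}")


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a single-band raster, masking declared nodata cells."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GridFormatError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return _read_geotiff(path) if fmt == "geotiff" else _read_ascii(path)


def write_grid(grid: Grid, path: str | Path, format: str | None = None,
               nodata: float = -9999.0) -> Path:
    """Write a Grid; invalid cells receive the nodata sentinel."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GridFormatError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    if fmt == "geotiff":
        _write_geotiff(grid, path, nodata=nodata)
    else:
        _write_ascii(grid, path, nodata=nodata)
    return path


# ----------------------------------------------------------------------------
# Stack validation and area accounting
# ----------------------------------------------------------------------------

def assert_aligned(stack: IndicatorStack) -> IndicatorStack:
    """Validate that every layer shares geometry; return the stack unchanged.

    Raises :class:`AlignmentError` naming the first offending layer.
    """
    if len(stack) < 1:
        raise AlignmentError("stack has no layers")
    ref_name = stack.names[0]
    ref = stack.layers[ref_name]
    for name, g in stack:
        if g.shape != ref.shape:
            raise AlignmentError(
                f"layer {name!r} shape {g.shape} != {ref.shape} of {ref_name!r}")
        if abs(g.cell_size - ref.cell_size) > 1e-9:
            raise AlignmentError(
                f"layer {name!r} cell_size {g.cell_size} != {ref.cell_size}")
        if not ref.same_geometry(g):
            raise AlignmentError(
                f"layer {name!r} origin {g.origin} != {ref.origin} of {ref_name!r}")
    stack.common_mask()  # materialize once so degenerate stacks fail early
    return stack


def class_areas(grid: Grid) -> dict[int, float]:
    """Area in m² per category code over the valid cells.

    The areas partition the valid region: their sum is exactly
    ``n_valid * cell_size**2``.
    """
    if grid.n_valid == 0:
        raise ValueError("grid has no valid cells")
    vals = grid.valid_values()
    codes, counts = np.unique(vals, return_counts=True)
    cell_area = grid.cell_area()
    return {int(c): float(n) * cell_area for c, n in zip(codes, counts)}


# ----------------------------------------------------------------------------
# Zones from GeoJSON
# ----------------------------------------------------------------------------

def load_zones_geojson(path: str | Path, template: Grid,
                       name_property: str = "name",
                       code_property: str = "code") -> ZoneMap:
    """Rasterize GeoJSON polygons onto the template geometry.

    Membership uses the cell-center-in-polygon rule; cells whose center falls
    in no polygon are masked out of the zone grid.
    """
    from shapely import contains_xy
    from shapely.geometry import shape as shapely_shape

    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        raise ValueError(f"{path}: GeoJSON has no features")

    xs, ys = template.cell_centers()
    zone_codes = np.zeros(template.shape, dtype=float)
    assigned = np.zeros(template.shape, dtype=bool)
    names: dict[int, str] = {}
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        code = int(props.get(code_property, i + 1))
        names[code] = str(props.get(name_property, f"zone_{code}"))
        geom = shapely_shape(feat["geometry"])
        inside = contains_xy(geom, xs, ys)
        take = inside & ~assigned  # first feature wins on overlap
        zone_codes[take] = code
        assigned |= take

    mask = assigned & template.mask
    zones = template.with_values(zone_codes, mask)
    present = set(np.unique(zone_codes[mask]).astype(int).tolist())
    names = {c: n for c, n in names.items() if c in present}
    return ZoneMap(zones=zones, names=names)
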