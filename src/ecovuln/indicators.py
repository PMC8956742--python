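"""Indicator standardization and station interpolation.

Every evaluation indicator is mapped onto a common 0-10 vulnerability scale
before entering the principal-component step.  Quantitative indicators use
range standardization:

    positive polarity (more is more vulnerable):
        Y = 10 (X - Xmin) / (Xmax - Xmin)
    negative polarity (more is less vulnerable):
        Y = 10 (Xmax - X) / (Xmax - Xmin)

so a larger Y always means a more vulnerable cell.  Categorical indicators
(land-use type) are scored by a hierarchical assignment table; the default
table scores forest and water 2, grassland 4, cultivated land 6 and
construction land 8.

Station measurements (climate, socio-economic point data) are spatialized by
inverse-distance-weighted (IDW) interpolation onto the reference grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .grids import Grid

__all__ = [
    "StandardizedLayer",
    "StationSet",
    "DEFAULT_LANDUSE_SCORES",
    "standardize",
    "assign_categories",
    "idw_interpolate",
    "read_stations_csv",
]

#: Hierarchical assignment of land-use categories to 0-10 vulnerability
#: scores.  Water scores low because open water in a forest mosaic is a
#: stable, undisturbed land cover, not a stressed one.
DEFAULT_LANDUSE_SCORES: dict[str, float] = {
    "forest": 2.0,
    "grassland": 4.0,
    "cultivated": 6.0,
    "construction": 8.0,
    "water": 2.0,
}


@dataclass
class StandardizedLayer:
    """A 0-10 standardized indicator surface.

    ``x_min``/``x_max`` record the extremes actually used, so cross-epoch
    re-standardization and provenance stay auditable.
    """

    grid: Grid
    source_name: str
    polarity: str
    x_min: float | None = None
    x_max: float | None = None

    def __post_init__(self) -> None:
        vals = self.grid.valid_values()
        if vals.size and (vals.min() < -1e-9 or vals.max() > 10 + 1e-9):
            raise ValueError(
                f"{self.source_name}: standardized values outside [0, 10]")


@dataclass
class StationSet:
    """Point measurements in map coordinates: rows of (x, y, value)."""

    points: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of x, y, value")
        if len(self.points) < 1:
            raise ValueError("StationSet needs at least one station")
        if not np.all(np.isfinite(self.points[:, :2])):
            raise ValueError("station coordinates must be finite")
        # identical coordinates with conflicting values are ambiguous
        coords = self.points[:, :2]
        _, inverse = np.unique(coords, axis=0, return_inverse=True)
        for g in range(inverse.max() + 1):
            vals = self.points[inverse == g, 2]
            if len(vals) > 1 and not np.allclose(vals, vals[0]):
                xy = coords[inverse == g][0]
                raise ValueError(
                    f"duplicate station at {tuple(xy)} with conflicting values")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def values(self) -> np.ndarray:
        return self.points[:, 2]


def read_stations_csv(path: str | Path) -> StationSet:
    """Read stations from a CSV with required header columns x, y, value."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y", "value"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns x, y, value")
        rows = [(float(r["x"]), float(r["y"]), float(r["value"])) for r in reader]
    return StationSet(points=np.array(rows, dtype=float))


def standardize(grid: Grid, polarity: str,
                x_min: float | None = None,
                x_max: float | None = None,
                name: str = "") -> StandardizedLayer:
    """Range-standardize a numeric indicator onto the 0-10 scale.

    Extremes default to the min/max over the grid's valid cells; explicit
    overrides support cross-epoch comparability.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be positive or negative, got {polarity!r}")
    vals = grid.valid_values()
    if vals.size == 0:
        raise ValueError("cannot standardize a grid with no valid cells")
    lo = float(vals.min()) if x_min is None else float(x_min)
    hi = float(vals.max()) if x_max is None else float(x_max)
    if not hi > lo:
        raise ValueError(f"degenerate range: x_max ({hi}) must exceed x_min ({lo})")

    out = np.zeros_like(np.asarray(grid.values, dtype=float))
    x = np.asarray(grid.values, dtype=float)
    if polarity == "positive":
        out = 10.0 * (x - lo) / (hi - lo)
    else:
        out = 10.0 * (hi - x) / (hi - lo)
    out = np.clip(out, 0.0, 10.0)  # overrides may be inside the data range
    return StandardizedLayer(
        grid=grid.with_values(out),
        source_name=name,
        polarity=polarity,
        x_min=lo,
        x_max=hi,
    )


def assign_categories(grid: Grid, table: Mapping[int, float] | Mapping[str, float],
                      code_names: Mapping[int, str] | None = None,
                      name: str = "") -> StandardizedLayer:
    """Score a categorical grid by table lookup.

    ``table`` maps either integer codes or category names to scores; in the
    latter case ``code_names`` translates raster codes to those names.
    """
    if code_names is not None:
        table = {code: table[nm] for code, nm in code_names.items() if nm in table}
    lookup = {int(k): float(v) for k, v in table.items()}

    codes = np.unique(grid.valid_values()).astype(int)
    unknown = sorted(set(codes.tolist()) - set(lookup))
    if unknown:
        raise ValueError(f"category codes without assignment: {unknown}")

    out = np.zeros(grid.shape, dtype=float)
    vals = np.asarray(grid.values)
    for code, score in lookup.items():
        out[vals == code] = score
    return StandardizedLayer(
        grid=grid.with_values(out),
        source_name=name,
        polarity="categorical",
    )


def idw_interpolate(stations: StationSet, template: Grid,
                    power: float = 2.0,
                    k_neighbors: int | None = 12) -> Grid:
    """Inverse-distance-weighted interpolation of stations onto a grid.

    Each cell value is the weighted mean of the ``k_neighbors`` nearest
    station values with weights d**(-power); a cell whose center coincides
    with a station takes that station's value exactly.  ``k_neighbors=None``
    uses every station.  Ties in the nearest-neighbour selection are broken
    by station input order (stable).
    """
    if power <= 0:
        raise ValueError("power must be positive")
    n = len(stations)
    k = n if k_neighbors is None else min(int(k_neighbors), n)
    if k < 1:
        raise ValueError("k_neighbors must be at least 1")

    xs, ys = template.cell_centers()
    pts = np.column_stack([xs.ravel(), ys.ravel()])

    tree = cKDTree(stations.xy)
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    svals = stations.values[idx]

    out = np.empty(len(pts))
    exact = dist[:, 0] == 0.0
    out[exact] = svals[exact, 0]
    rest = ~exact
    if rest.any():
        w = dist[rest] ** (-power)
        out[rest] = (w * svals[rest]).sum(axis=1) / w.sum(axis=1)
    return template.with_values(out.reshape(template.shape))
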