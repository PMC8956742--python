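"""Patch delineation and landscape-level pattern metrics.

A *patch* is a maximal connected region of same-class cells (8-neighbour
connectivity by default, the common convention).  Five landscape-level
metrics summarize fragmentation and diversity of a categorical map:

NP
    number of patches.
LPI
    largest patch index, 100 * (largest patch area) / (landscape area), %.
SHDI
    Shannon diversity of the class area proportions p_c, -sum p_c ln p_c,
    in nats; 0 for a single class, at most ln(number of classes).
DIVISION
    landscape division, 1 - sum over patches of (a / A)^2 — the probability
    that two randomly drawn cells fall in different patches; 0 for one
    patch, approaching 1 under extreme fragmentation.
AI
    aggregation index, 100 * sum_c P_c * g_cc / max_g_cc, where g_cc counts
    the like adjacencies of class c (each shared cell edge once, rook
    neighbourhood) and max_g_cc is the largest adjacency count the class's
    cell total could achieve when packed into a square-ish block; 100 for a
    maximally clumped landscape, 0 when no two like cells touch.

Metric surfaces come from a moving window: each output cell holds the metric
of the square window centred there, with edge cells (where the window leaves
the grid) masked rather than padded — padding would distort adjacency counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid

__all__ = [
    "PatchSet",
    "MetricsRecord",
    "METRIC_NAMES",
    "label_patches",
    "compute_metrics",
    "moving_window",
    "max_like_adjacencies",
]

METRIC_NAMES = ("np", "lpi", "ai", "division", "shdi")

_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class PatchSet:
    """Connected-component partition of a categorical grid."""

    labels: Grid                 # patch id per cell (0 = invalid)
    patch_table: dict[int, tuple[int, float, int]]  # id -> (class, area m², cells)
    connectivity: int
    _class_grid: Grid | None = None  # source map, kept for adjacency counts

    @property
    def n_patches(self) -> int:
        return len(self.patch_table)


@dataclass
class MetricsRecord:
    """The five landscape-level metrics of one map or window."""

    np: int
    lpi: float        # % of landscape
    ai: float         # % in [0, 100]
    division: float   # [0, 1)
    shdi: float       # nats

    def as_dict(self) -> dict[str, float]:
        return {"np": self.np, "lpi": self.lpi, "ai": self.ai,
                "division": self.division, "shdi": self.shdi}


def label_patches(grid: Grid, connectivity: int = 8) -> PatchSet:
    """Label maximal connected same-class regions.

    Patch ids are assigned class by class in ascending code order, then in
    scan order within a class, so identical inputs always label identically.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if grid.n_valid == 0:
        raise ValueError("grid has no valid cells")

    structure = _STRUCTURE[connectivity]
    vals = np.asarray(grid.values)
    labels = np.zeros(grid.shape, dtype=int)
    table: dict[int, tuple[int, float, int]] = {}
    next_id = 1
    cell_area = grid.cell_area()
    for code in np.unique(vals[grid.mask]):
        member = (vals == code) & grid.mask
        lab, n = ndimage.label(member, structure=structure)
        for p in range(1, n + 1):
            cells = int((lab == p).sum())
            labels[lab == p] = next_id
            table[next_id] = (int(code), cells * cell_area, cells)
            next_id += 1
    return PatchSet(
        labels=grid.with_values(labels.astype(float)),
        patch_table=table,
        connectivity=connectivity,
        _class_grid=grid,
    )


def max_like_adjacencies(m: int) -> int:
    """Largest number of shared edges m cells can have on a square lattice.

    Achieved by filling an s x s square (s = floor(sqrt(m))) and wrapping the
    remainder along its side: 2s(s-1) for a perfect square, plus
    2(m - s^2) - 1 if the remainder fits one extra row/column segment,
    else 2(m - s^2) - 2.
    """
    if m < 1:
        raise ValueError("m must be positive")
    s = math.isqrt(m)
    rem = m - s * s
    base = 2 * s * (s - 1)
    if rem == 0:
        return base
    if rem <= s:
        return base + 2 * rem - 1
    return base + 2 * rem - 2


def _like_adjacency_counts(grid: Grid) -> dict[int, int]:
    """Single-count like adjacencies per class (rook neighbourhood)."""
    vals = np.asarray(grid.values)
    mask = grid.mask
    counts: dict[int, int] = {}
    # horizontal neighbours
    same = (vals[:, :-1] == vals[:, 1:]) & mask[:, :-1] & mask[:, 1:]
    for code in np.unique(vals[:, :-1][same]):
        counts[int(code)] = counts.get(int(code), 0) + int(
            (same & (vals[:, :-1] == code)).sum())
    # vertical neighbours
    same = (vals[:-1, :] == vals[1:, :]) & mask[:-1, :] & mask[1:, :]
    for code in np.unique(vals[:-1, :][same]):
        counts[int(code)] = counts.get(int(code), 0) + int(
            (same & (vals[:-1, :] == code)).sum())
    return counts


def compute_metrics(patches: PatchSet) -> MetricsRecord:
    """The five landscape-level metrics of a labelled map."""
    if patches.n_patches < 1:
        raise ValueError("empty patch set")
    table = patches.patch_table
    areas = np.array([a for (_, a, _) in table.values()])
    classes = np.array([c for (c, _, _) in table.values()])
    total = areas.sum()

    n_patches = len(table)
    lpi = 100.0 * areas.max() / total
    division = 1.0 - float(((areas / total) ** 2).sum())

    class_area = {}
    class_cells = {}
    for c, a, m in table.values():
        class_area[c] = class_area.get(c, 0.0) + a
        class_cells[c] = class_cells.get(c, 0) + m
    p = np.array([a / total for a in class_area.values()])
    shdi = float(-(p * np.log(p)).sum())

    g = _like_adjacency_counts(patches._class_grid)
    ai = 0.0
    for c, cells in class_cells.items():
        max_g = max_like_adjacencies(cells)
        if max_g == 0:  # single-cell class cannot aggregate
            continue
        ai += (class_area[c] / total) * (g.get(c, 0) / max_g)
    ai *= 100.0

    return MetricsRecord(np=n_patches, lpi=float(lpi), ai=float(ai),
                         division=float(division), shdi=shdi)


def metrics_of_grid(grid: Grid, connectivity: int = 8) -> MetricsRecord:
    """Convenience: label then measure in one call."""
    return compute_metrics(label_patches(grid, connectivity))


def _crop(grid: Grid, r0: int, c0: int, size: int) -> Grid:
    return Grid(
        values=np.asarray(grid.values)[r0:r0 + size, c0:c0 + size],
        mask=grid.mask[r0:r0 + size, c0:c0 + size],
        cell_size=grid.cell_size,
        origin=(grid.origin[0] + c0 * grid.cell_size,
                grid.origin[1] - r0 * grid.cell_size),
        crs_tag=grid.crs_tag,
    )


def moving_window(grid: Grid, window: int = 33, stride: int = 1,
                  connectivity: int = 8,
                  metrics: tuple[str, ...] = METRIC_NAMES) -> dict[str, Grid]:
    """Metric surfaces from a square moving window.

    Each evaluated cell holds the metric of the window centred on it; cells
    whose window leaves the grid, skipped strides, and windows with no valid
    cells are masked.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3:
        raise ValueError("window must be at least 3 cells")
    nrows, ncols = grid.shape
    if window > nrows or window > ncols:
        raise ValueError("window exceeds grid extent")
    half = window // 2

    out = {m: np.full(grid.shape, np.nan) for m in metrics}
    out_mask = np.zeros(grid.shape, dtype=bool)
    for r in range(half, nrows - half, stride):
        for c in range(half, ncols - half, stride):
            sub = _crop(grid, r - half, c - half, window)
            if sub.n_valid == 0:
                continue
            rec = compute_metrics(label_patches(sub, connectivity)).as_dict()
            for m in metrics:
                out[m][r, c] = rec[m]
            out_mask[r, c] = True

    return {m: grid.with_values(np.nan_to_num(out[m]), out_mask & grid.mask)
            for m in metrics}
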