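"""Per-pixel temporal trend of the vulnerability index and its classification.

For each cell the least-squares slope of EVI against the 1-based epoch index
i = 1..n is

    K = (n * sum(i * EVI_i) - sum(i) * sum(EVI_i))
        / (n * sum(i^2) - sum(i)^2)

A positive K means the cell's vulnerability index is rising over the study
period, a negative K that it is falling.  The slope surface is then cut into
five change levels with Jenks natural breaks — the 1-D partition minimizing
total within-class sum of squared deviations, computed exactly by dynamic
programming over the sorted values (Fisher's optimal partition).  Among
equal-cost partitions the one with the smallest first break is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid

__all__ = ["TrendSurface", "fit_trend", "jenks_breaks", "jenks_classify",
           "classify_trend"]


@dataclass
class TrendSurface:
    """Slope surface plus (optionally) its natural-breaks classification."""

    slope: Grid
    n_years: int
    classes: Grid | None = None
    breaks: np.ndarray | None = None


def fit_trend(evi_by_year: dict) -> TrendSurface:
    """Cellwise least-squares slope of EVI across epochs.

    ``evi_by_year`` is an ordered mapping year -> Grid; the regression runs
    against the 1-based position of each epoch in that order, not against
    calendar years.  Valid where all epochs are valid.
    """
    grids = list(evi_by_year.values())
    n = len(grids)
    if n < 2:
        raise ValueError("need at least two epochs to fit a trend")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError("EVI surfaces must share geometry across epochs")

    idx = np.arange(1, n + 1, dtype=float)
    si, sii = idx.sum(), (idx ** 2).sum()
    stack = np.stack([np.asarray(g.values, dtype=float) for g in grids])  # (n, r, c)
    s_y = stack.sum(axis=0)
    s_iy = np.tensordot(idx, stack, axes=(0, 0))
    slope = (n * s_iy - si * s_y) / (n * sii - si ** 2)

    mask = np.logical_and.reduce([g.mask for g in grids])
    return TrendSurface(slope=ref.with_values(slope, mask), n_years=n)


# ----------------------------------------------------------------------------
# Fisher-Jenks natural breaks
# ----------------------------------------------------------------------------

def _jenks_dp(vals: np.ndarray, n_classes: int) -> np.ndarray:
    """Exact Fisher dynamic programme on sorted values; returns start
    indices of classes 2..n_classes."""
    n = vals.size
    c1 = np.concatenate([[0.0], np.cumsum(vals)])
    c2 = np.concatenate([[0.0], np.cumsum(vals ** 2)])

    INF = float("inf")
    cost = np.full((n_classes + 1, n + 1), INF)
    cut = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        prev = cost[k - 1]
        for j in range(k, n + 1):
            # last class covers vals[i..j-1] for i in [k-1, j)
            i = np.arange(k - 1, j)
            m = j - i
            s = c1[j] - c1[i]
            ss_last = (c2[j] - c2[i]) - s * s / m
            cand = prev[i] + ss_last
            best = cand.min()
            # earliest start wins on (near-)ties -> smallest first break
            arg = int(np.nonzero(cand <= best + 1e-12)[0][0])
            cost[k, j] = cand[arg]
            cut[k, j] = k - 1 + arg

    starts = []
    j = n
    for k in range(n_classes, 0, -1):
        i = cut[k, j]
        starts.append(int(i))
        j = i
    starts = starts[::-1]  # ascending; starts[0] == 0
    return np.array(starts[1:], dtype=int)


def jenks_breaks(values: np.ndarray, n_classes: int = 5,
                 max_n: int = 4000) -> np.ndarray:
    """Optimal 1-D class breaks minimizing within-class sum of squares.

    Returns the ``n_classes - 1`` interior break values, each expressed as
    the first (smallest) value of its class.  The dynamic programme is exact;
    for inputs longer than ``max_n`` it runs on a deterministic sample at
    evenly spaced ranks of the sorted values (the quadratic-cost programme is
    otherwise impractical on full rasters), which is the standard large-input
    treatment for natural breaks.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(vals)
    if uniq.size < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct values, have {uniq.size}")
    if vals.size > max_n:
        ranks = np.linspace(0, vals.size - 1, max_n).round().astype(int)
        sample = vals[ranks]
        if np.unique(sample).size < n_classes:  # heavy ties; fall back to uniques
            sample = uniq
        starts = _jenks_dp(sample, n_classes)
        return sample[starts]
    starts = _jenks_dp(vals, n_classes)
    return vals[starts]


def jenks_classify(grid: Grid, n_classes: int = 5) -> tuple[Grid, np.ndarray]:
    """Classify a surface into natural-breaks classes 1..n_classes.

    Class c holds values in [break_{c-1}, break_c); class codes increase
    with value.
    """
    vals = grid.valid_values()
    breaks = jenks_breaks(vals, n_classes)
    codes = np.digitize(np.asarray(grid.values, dtype=float), breaks) + 1
    return grid.with_values(codes.astype(float)), breaks


def classify_trend(surface: TrendSurface, n_classes: int = 5) -> TrendSurface:
    """Attach the natural-breaks change-level classification to a slope
    surface."""
    classes, breaks = jenks_classify(surface.slope, n_classes)
    surface.classes = classes
    surface.breaks = breaks
    return surface
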