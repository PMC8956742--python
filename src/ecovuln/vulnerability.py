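"""Vulnerability index construction, grading, and regional aggregation.

The ecological vulnerability index (EVI) of a cell is the contribution-rate
weighted sum of its retained principal-component scores:

    EVI = r1*Y1 + r2*Y2 + ... + rk*Yk

with the r_i taken directly from the eigenvalue shares (not renormalized over
the retained k).  Because epochs are decomposed separately, raw EVI surfaces
are not comparable across years; the standardized index

    SVI = 10 (EVI - EVImin) / (EVImax - EVImin)

pools the extremes over *all* epochs, landing every epoch on a common 0-10
scale.  The SVI is cut into five grades with equal-width intervals
(boundaries 2, 4, 6, 8; lower-closed, top class closed at 10):

    I  micro    [0, 2)      IV severe   [6, 8)
    II mild     [2, 4)      V  extreme  [8, 10]
    III moderate [4, 6)

and the comprehensive ecological vulnerability index of a region is the
area-weighted mean grade value

    CEVI = sum_i L_i * A_i / S    in [1, 5],

computed over the whole landscape or per zone (cell-center membership).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, ZoneMap, class_areas
from .spca import PcaResult

__all__ = [
    "VulnSurface",
    "GradingScheme",
    "VulnGrade",
    "GRADE_NAMES",
    "compute_evi",
    "standardize_svi",
    "classify",
    "compute_cevi",
    "mean_cevi",
    "cevi_table",
]

GRADE_NAMES = {1: "micro", 2: "mild", 3: "moderate", 4: "severe", 5: "extreme"}


@dataclass
class VulnSurface:
    """Raw and standardized vulnerability surfaces for one epoch."""

    evi: Grid
    svi: Grid | None = None
    epoch: str = ""


@dataclass(frozen=True)
class GradingScheme:
    """Five-level grading of the 0-10 SVI scale."""

    breaks: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    labels: tuple[str, ...] = ("micro", "mild", "moderate", "severe", "extreme")

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.labels) - 1:
            raise ValueError("need exactly one more label than break")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")


@dataclass
class VulnGrade:
    """Graded surface plus area accounting and the CEVI scalar."""

    classes: Grid                       # integer codes 1..5
    area_by_class: dict[int, float]     # m² per grade
    proportions: dict[int, float]       # A_i / S
    cevi: float
    scheme: GradingScheme = field(default_factory=GradingScheme)


def compute_evi(pca: PcaResult, k: int | None = None) -> Grid:
    """Weighted sum of the first k component-score rasters.

    Weights are the un-renormalized contribution rates, so dropping the tail
    components drops their (small) variance share rather than inflating the
    retained ones.
    """
    if k is None:
        k = pca.n_components
    if not 1 <= k <= pca.n_components:
        raise ValueError(f"k={k} outside [1, {pca.n_components}]")
    template = pca.scores[0]
    acc = np.zeros(template.shape)
    for i in range(k):
        acc += pca.contribution_rates[i] * np.asarray(pca.scores[i].values, dtype=float)
    return template.with_values(acc)


def standardize_svi(evi_by_year: dict[str, Grid] | dict[int, Grid]) -> dict:
    """Rescale per-epoch EVI surfaces to [0, 10] with pooled extremes.

    The minimum and maximum are taken over all epochs' valid cells jointly,
    so cross-epoch ordering of EVI is preserved exactly and the pooled argmin
    maps to 0, the pooled argmax to 10.
    """
    if not evi_by_year:
        raise ValueError("no epochs given")
    grids = list(evi_by_year.values())
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError("EVI surfaces must share geometry across epochs")
    lo = min(float(g.valid_values().min()) for g in grids)
    hi = max(float(g.valid_values().max()) for g in grids)
    if not hi > lo:
        raise ValueError("degenerate EVI range: pooled max equals pooled min")
    out = {}
    for year, g in evi_by_year.items():
        svi = 10.0 * (np.asarray(g.values, dtype=float) - lo) / (hi - lo)
        out[year] = g.with_values(svi)
    return out


def classify(svi: Grid, scheme: GradingScheme = GradingScheme()) -> VulnGrade:
    """Cut an SVI surface into the five grades and account class areas.

    Intervals are lower-closed ([2, 4) etc.); the top class is closed at 10
    so the pooled maximum belongs to grade V.
    """
    vals = svi.valid_values()
    if vals.size == 0:
        raise ValueError("SVI grid has no valid cells")
    if vals.min() < -1e-9 or vals.max() > 10 + 1e-9:
        raise ValueError("SVI values must lie in [0, 10]")

    # np.digitize with right=False gives lower-closed bins; values equal to
    # 10 fall past the last break into the top class already.
    codes = np.digitize(np.asarray(svi.values, dtype=float), scheme.breaks) + 1
    classes = svi.with_values(codes.astype(float))

    areas = class_areas(classes)
    areas = {int(c): areas.get(c, 0.0) for c in range(1, len(scheme.labels) + 1)
             if c in areas}
    total = sum(areas.values())
    proportions = {c: a / total for c, a in areas.items()}
    cevi = sum(c * p for c, p in proportions.items())
    return VulnGrade(classes=classes, area_by_class=areas,
                     proportions=proportions, cevi=cevi, scheme=scheme)


def compute_cevi(grade: VulnGrade, zones: ZoneMap | None = None):
    """Area-weighted mean grade, overall or per zone.

    With all cells sharing one cell area this equals the plain mean of the
    per-cell grade codes over the region.  Empty zones are omitted with a
    warning.
    """
    if zones is None:
        return grade.cevi

    cls = grade.classes
    out: dict[str, float] = {}
    zvals = np.asarray(zones.zones.values)
    joint = cls.mask & zones.zones.mask
    for code in zones.codes():
        sel = joint & (zvals == code)
        n = int(sel.sum())
        if n == 0:
            import warnings
            warnings.warn(f"zone {zones.names[code]!r} has no valid cells; omitted")
            continue
        out[zones.names[code]] = float(np.asarray(cls.values)[sel].mean())
    return out


def mean_cevi(values_by_year) -> float:
    """Arithmetic mean of per-epoch CEVI values (the 'Mean' row/column)."""
    vals = np.asarray(list(values_by_year), dtype=float)
    if vals.size == 0:
        raise ValueError("no CEVI values")
    return float(vals.mean())


def cevi_table(per_zone_by_year: dict[str, dict[str, float]],
               overall_by_year: dict[str, float]) -> pd.DataFrame:
    """Zones x years CEVI table with a Total column and a Mean row,
    rounded to 2 decimals (half-up)."""
    from decimal import Decimal, ROUND_HALF_UP

    def r2(x: float) -> float:
        return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    years = list(per_zone_by_year)
    zone_names = list(next(iter(per_zone_by_year.values())))
    rows = {}
    for year in years:
        row = {z: r2(per_zone_by_year[year].get(z, float("nan"))) for z in zone_names}
        row["Total"] = r2(overall_by_year[year])
        rows[year] = row
    df = pd.DataFrame(rows).T
    df.loc["Mean"] = [r2(mean_cevi(df[c].dropna())) for c in df.columns]
    return df
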