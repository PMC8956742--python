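"""Contribution of landscape-pattern metrics to the vulnerability index.

The link between landscape structure and vulnerability is quantified by a
partial-regression decomposition.  With response Y (the vulnerability index
sampled over window units) and predictors X_1..X_k (NP, LPI, DIVISION, AI,
SHDI), the full ordinary-least-squares model yields the regression sum of
squares

    U = sum (yhat - ybar)^2 .

Refitting with X_i removed yields U_i, and the partial regression sum of
squares of X_i is

    P_i = U - U_i  >= 0   (nested models; both keep the intercept),

its share of the total being the contribution rate

    S_i = 100 * P_i / sum_j P_j   (%).

A large S_i means predictor i carries explanatory power the other predictors
cannot replace.  Per-metric simple regressions (slope, intercept, Pearson r)
are also provided for scatter-plot style reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = [
    "RegressionDesign",
    "ContributionTable",
    "fit_ols",
    "partial_contributions",
    "simple_regressions",
    "build_design_from_windows",
    "contribution_rates_from_partials",
]


@dataclass
class RegressionDesign:
    """Samples for the metric-vulnerability regression."""

    y: np.ndarray                  # (n,)
    X: np.ndarray                  # (n, k)
    predictor_names: list[str]
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n_samples, k) matching y")
        if len(self.predictor_names) != self.X.shape[1]:
            raise ValueError("one name per predictor required")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise ValueError("design contains missing/non-finite values")
        n, k = self.X.shape
        if n < k + 2:
            raise ValueError(f"need at least {k + 2} samples for {k} predictors")

    @property
    def n_samples(self) -> int:
        return self.y.size

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def drop(self, i: int) -> "RegressionDesign":
        keep = [j for j in range(self.n_predictors) if j != i]
        return RegressionDesign(
            y=self.y, X=self.X[:, keep],
            predictor_names=[self.predictor_names[j] for j in keep],
            sample_ids=self.sample_ids,
        )


@dataclass
class ContributionTable:
    """Full/reduced regression sums of squares and contribution rates."""

    U: float                        # full-model regression SS
    U_reduced: np.ndarray           # U_i with predictor i removed
    partial_ss: np.ndarray          # P_i = U - U_i
    contribution_pct: np.ndarray    # S_i = 100 P_i / sum P
    coefficients: np.ndarray        # intercept first, then slopes
    predictor_names: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "partial_ss": self.partial_ss,
            "contribution_pct": self.contribution_pct,
            "coefficient": self.coefficients[1:],
        }, index=self.predictor_names)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coefficients, regression SS)."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("design matrix is singular (exact collinearity)")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ beta
    U = float(((yhat - y.mean()) ** 2).sum())
    return beta, U


def fit_ols(design: RegressionDesign) -> tuple[np.ndarray, float]:
    """Full-model OLS fit: coefficients (intercept first) and regression SS U."""
    return _ols(design.y, design.X)


def partial_contributions(design: RegressionDesign) -> ContributionTable:
    """Leave-one-out partial regression SS and contribution rates.

    Each reduced model drops one predictor but keeps the intercept, so the
    models are nested and every P_i is non-negative.
    """
    k = design.n_predictors
    if k < 2:
        raise ValueError("need at least two predictors to decompose")
    beta, U = fit_ols(design)
    U_red = np.empty(k)
    for i in range(k):
        try:
            _, U_red[i] = fit_ols(design.drop(i))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"reduced model without {design.predictor_names[i]!r} is "
                f"singular") from exc
    partial = U - U_red
    partial = np.clip(partial, 0.0, None)  # guard round-off at ~1e-12
    return ContributionTable(
        U=U,
        U_reduced=U_red,
        partial_ss=partial,
        contribution_pct=contribution_rates_from_partials(partial),
        coefficients=beta,
        predictor_names=list(design.predictor_names),
    )


def contribution_rates_from_partials(partial_ss: np.ndarray | list[float]) -> np.ndarray:
    """S_i = 100 * P_i / sum(P), in percent."""
    p = np.asarray(partial_ss, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("partial sums of squares are all zero")
    return 100.0 * p / total


def simple_regressions(design: RegressionDesign) -> pd.DataFrame:
    """Univariate fit of y on each predictor: slope, intercept, Pearson r."""
    from scipy import stats

    if design.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rows = {}
    for i, name in enumerate(design.predictor_names):
        x = design.X[:, i]
        if np.ptp(x) == 0:
            warnings.warn(f"predictor {name!r} has zero variance; skipped")
            continue
        res = stats.linregress(x, design.y)
        rows[name] = {"slope": res.slope, "intercept": res.intercept,
                      "r": res.rvalue, "p_value": res.pvalue}
    return pd.DataFrame(rows).T


def build_design_from_windows(metric_surfaces: dict[str, Grid], evi: Grid,
                              window: int, stride: int | None = None,
                              predictor_order: tuple[str, ...] =
                              ("np", "lpi", "division", "ai", "shdi")) -> RegressionDesign:
    """Pair window-centre metric samples with the window-mean EVI.

    Sampling units are the evaluated cells of the moving-window metric
    surfaces (already strided there); the response at a unit is the mean EVI
    over that unit's window footprint.
    """
    names = [m for m in predictor_order if m in metric_surfaces]
    if not names:
        raise ValueError("no metric surfaces supplied")
    ref = metric_surfaces[names[0]]
    sample_mask = ref.mask.copy()
    for m in names:
        sample_mask &= metric_surfaces[m].mask
    rows, cols = np.nonzero(sample_mask)
    if stride is not None:
        keep = (rows % stride == 0) & (cols % stride == 0)
        rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        raise ValueError("no sampling units: masks do not overlap")

    half = window // 2
    evi_vals = np.asarray(evi.values, dtype=float)
    y = np.empty(rows.size)
    for s, (r, c) in enumerate(zip(rows, cols)):
        sub = evi_vals[r - half:r + half + 1, c - half:c + half + 1]
        subm = evi.mask[r - half:r + half + 1, c - half:c + half + 1]
        y[s] = sub[subm].mean()
    X = np.column_stack([
        np.asarray(metric_surfaces[m].values, dtype=float)[rows, cols]
        for m in names
    ])
    return RegressionDesign(y=y, X=X, predictor_names=names,
                            sample_ids=list(zip(rows.tolist(), cols.tolist())))
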