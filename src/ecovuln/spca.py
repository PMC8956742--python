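"""Spatial principal component analysis of an indicator stack.

The stack's standardized layers are flattened over the common validity mask
into an (n_cells x n_indicators) data matrix.  PCA is run on the covariance
matrix of that matrix (the layers already share the 0-10 scale, so no further
rescaling): eigenvalues are sorted descending, each eigenvalue's share of the
trace is its contribution rate

    r_i = lambda_i / sum(lambda),

and components are retained until the cumulative contribution rate reaches a
threshold (90% by default).  Pixel scores are the mean-centered data projected
onto the eigenvectors, written back to the stack geometry as score rasters.

Eigenvector sign is arbitrary in the decomposition; here each loading
vector is flipped so its largest-magnitude entry is positive, which makes
score rasters reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid, IndicatorStack, assert_aligned

__all__ = [
    "PcaResult",
    "fit_spca",
    "contribution_rates",
    "select_components",
    "loadings_frame",
    "eigen_table",
]


@dataclass
class PcaResult:
    """Eigendecomposition bookkeeping plus per-component score rasters."""

    eigenvalues: np.ndarray          # descending, >= 0
    loadings: np.ndarray             # (n_indicators, n_components)
    contribution_rates: np.ndarray   # r_i, sums to 1
    cumulative_rates: np.ndarray     # running sums of r_i
    scores: list[Grid]               # per-component pixel score rasters
    indicator_names: list[str]
    means: np.ndarray                # per-indicator means used for centering

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_names)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def contribution_rates(eigenvalues: np.ndarray | list[float]) -> np.ndarray:
    """Share of total variance carried by each component: r_i = l_i / sum(l)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("no eigenvalues")
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    return lam / total


def select_components(cumulative_rates_percent: np.ndarray | list[float],
                      threshold_percent: float = 90.0) -> int:
    """Smallest k whose cumulative contribution reaches the threshold.

    If the threshold is never reached (rounding in externally supplied
    tables), all components are kept with a warning.
    """
    cum = np.asarray(cumulative_rates_percent, dtype=float)
    if cum.size == 0:
        raise ValueError("empty cumulative rate list")
    if np.any(np.diff(cum) < -1e-9):
        raise ValueError("cumulative rates must be non-decreasing")
    reached = np.nonzero(cum >= threshold_percent - 1e-12)[0]
    if reached.size == 0:
        import warnings
        warnings.warn(
            f"cumulative contribution never reaches {threshold_percent}%; "
            "keeping all components")
        return int(cum.size)
    return int(reached[0]) + 1


def _stack_matrix(stack: IndicatorStack) -> tuple[np.ndarray, np.ndarray, list[str]]:
    assert_aligned(stack)
    mask = stack.common_mask()
    names = stack.names
    data = np.column_stack([
        np.asarray(stack.layers[n].values, dtype=float)[mask] for n in names
    ])
    return data, mask, names


def fit_spca(stack: IndicatorStack) -> PcaResult:
    """Eigendecompose the covariance matrix of the stack's valid cells.

    Component order is by descending eigenvalue; exact ties are resolved by
    lexicographic order of the loading vectors so symmetric synthetic inputs
    decompose deterministically.
    """
    data, mask, names = _stack_matrix(stack)
    n_cells, p = data.shape
    if p < 2:
        raise ValueError("need at least two layers for PCA")
    if n_cells < p:
        raise ValueError(
            f"only {n_cells} valid common cells for {p} indicators")

    stds = data.std(axis=0)
    if np.any(stds == 0):
        import warnings
        flat = [names[i] for i in np.nonzero(stds == 0)[0]]
        warnings.warn(f"constant layer(s) {flat}: zero variance component(s)")

    cov = np.cov(data, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)  # round-off can go slightly negative

    # deterministic handling of exactly tied eigenvalues
    i = 0
    while i < len(eigvals):
        j = i
        while j + 1 < len(eigvals) and eigvals[j + 1] == eigvals[i]:
            j += 1
        if j > i:
            block = eigvecs[:, i:j + 1]
            keys = [tuple(np.round(block[:, c], 12)) for c in range(block.shape[1])]
            sub = np.argsort([keys[c] for c in range(len(keys))])
            eigvecs[:, i:j + 1] = block[:, sub]
        i = j + 1

    # sign convention: a common-mode component (loadings share a direction,
    # |sum| well away from zero) is oriented with the vulnerability scale of
    # the inputs — positive loading sum — so EVI keeps "larger = more
    # vulnerable"; a contrast component (sum near zero, no vulnerability
    # orientation of its own) is oriented by its largest-magnitude loading,
    # which is the stable structural feature of such a vector.
    for c in range(eigvecs.shape[1]):
        v = eigvecs[:, c]
        s = v.sum()
        if abs(s) >= 0.25 * np.sqrt(len(v)):
            flip = s < 0
        else:
            flip = v[np.argmax(np.abs(v))] < 0
        if flip:
            eigvecs[:, c] = -v

    rates = contribution_rates(eigvals)
    cumulative = np.cumsum(rates)

    means = data.mean(axis=0)
    proj = (data - means) @ eigvecs  # (n_cells, p)

    template = stack.reference()
    scores: list[Grid] = []
    for c in range(p):
        surf = np.zeros(template.shape)
        surf[mask] = proj[:, c]
        scores.append(template.with_values(surf, mask))

    return PcaResult(
        eigenvalues=eigvals,
        loadings=eigvecs,
        contribution_rates=rates,
        cumulative_rates=cumulative,
        scores=scores,
        indicator_names=names,
        means=means,
    )


# ----------------------------------------------------------------------------
# Tabular exports
# ----------------------------------------------------------------------------

def eigen_table(result: PcaResult) -> pd.DataFrame:
    """Eigenvalue / contribution-rate / cumulative-rate table, one column
    per principal component (component columns, statistic rows)."""
    cols = [f"PC{i + 1}" for i in range(result.n_components)]
    return pd.DataFrame(
        [result.eigenvalues,
         100 * result.contribution_rates,
         100 * result.cumulative_rates],
        index=["eigenvalue", "contribution_rate_pct", "cumulative_rate_pct"],
        columns=cols,
    )


def loadings_frame(result: PcaResult, k: int | None = None) -> pd.DataFrame:
    """Loading matrix as indicator rows x component columns."""
    k = result.n_components if k is None else int(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(result.loadings[:, :k],
                        index=result.indicator_names, columns=cols)
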