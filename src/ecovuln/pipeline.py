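"""End-to-end orchestration of the vulnerability pipeline.

Stage order is fixed by the data dependencies: per-epoch standardization ->
spatial PCA -> EVI -> cross-epoch SVI (needs every epoch's EVI) ->
grading / CEVI -> temporal trend -> landscape metric surfaces ->
metric-contribution regression.  :func:`run_stacks` executes the chain on
in-memory stacks and returns a :class:`PipelineResult`; :func:`run_pipeline`
wraps it with YAML configuration, on-disk outputs, and a checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contribution as contrib
from . import landscape, spca, trend, vulnerability
from .grids import Grid, IndicatorMeta, IndicatorStack, ZoneMap, write_grid
from .indicators import assign_categories, standardize
from .synthetic_data import (CATEGORY_TABLES, ScenarioConfig, ScenarioBundle,
                             generate_scenario)

__all__ = ["PipelineParams", "PipelineResult", "run_stacks", "run_pipeline",
           "load_config"]


@dataclass
class PipelineParams:
    """Tunables of the analysis chain."""

    spca_threshold_pct: float = 90.0
    grading_breaks: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    window: int = 33
    window_stride: int = 4
    connectivity: int = 8
    category_tables: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CATEGORY_TABLES.items()})
    categorical_layer_for_metrics: str = "land_use"

    def __post_init__(self) -> None:
        if not 0 < self.spca_threshold_pct <= 100:
            raise ValueError("SPCA threshold must be in (0, 100]")


@dataclass
class PipelineResult:
    """Everything the chain computes, keyed by epoch where applicable."""

    standardized: dict[str, IndicatorStack]
    pca: dict[str, spca.PcaResult]
    k_selected: dict[str, int]
    evi: dict[str, Grid]
    svi: dict[str, Grid]
    grades: dict[str, vulnerability.VulnGrade]
    cevi_overall: dict[str, float]
    cevi_by_zone: dict[str, dict[str, float]] | None
    trend: trend.TrendSurface
    metric_surfaces: dict[str, dict[str, Grid]]
    global_metrics: pd.DataFrame
    contributions: dict[str, contrib.ContributionTable]
    simple_fits: dict[str, pd.DataFrame]


def standardize_stack(stack: IndicatorStack,
                      category_tables: dict[str, dict[int, float]],
                      extremes: dict[str, tuple[float, float]] | None = None,
                      ) -> IndicatorStack:
    """Standardize every layer of a raw stack onto the 0-10 scale.

    ``extremes`` optionally overrides the per-indicator (min, max) — used
    for cross-epoch comparability, where the extremes are pooled over all
    epochs so one physical value maps to one score in every year.
    """
    out = IndicatorStack(epoch=stack.epoch)
    for name, grid in stack:
        meta = stack.meta.get(name, IndicatorMeta("positive"))
        if meta.polarity == "categorical":
            table = category_tables.get(name)
            if table is None:
                raise ValueError(f"no category table for layer {name!r}")
            layer = assign_categories(grid, table, name=name)
        else:
            lo, hi = (extremes or {}).get(name, (None, None))
            layer = standardize(grid, meta.polarity, x_min=lo, x_max=hi,
                                name=name)
        out.add(name, layer.grid, meta)
    return out


def pooled_extremes(stacks: dict[str, IndicatorStack]) -> dict[str, tuple[float, float]]:
    """Per-indicator (min, max) pooled over every epoch's valid cells."""
    out: dict[str, tuple[float, float]] = {}
    for stack in stacks.values():
        for name, grid in stack:
            meta = stack.meta.get(name)
            if meta is not None and meta.polarity == "categorical":
                continue
            vals = grid.valid_values()
            lo, hi = float(vals.min()), float(vals.max())
            if name in out:
                lo = min(lo, out[name][0])
                hi = max(hi, out[name][1])
            out[name] = (lo, hi)
    return out


def _align_component_signs(pca_by_epoch: dict[str, spca.PcaResult]) -> None:
    """Orient every epoch's components consistently with the first epoch.

    Eigenvector sign is arbitrary within one decomposition; across epochs an
    inconsistent choice would flip a component's score surface between years
    and corrupt every cross-epoch quantity (SVI, trend).  Each later epoch's
    component is flipped when its loading vector points away from the
    reference epoch's matching component (negative dot product) — the usual
    sign alignment for longitudinal PCA.
    """
    epochs = list(pca_by_epoch)
    ref = pca_by_epoch[epochs[0]]
    for e in epochs[1:]:
        res = pca_by_epoch[e]
        n = min(ref.loadings.shape[1], res.loadings.shape[1])
        for c in range(n):
            if float(ref.loadings[:, c] @ res.loadings[:, c]) < 0:
                res.loadings[:, c] = -res.loadings[:, c]
                score = res.scores[c]
                res.scores[c] = score.with_values(
                    -np.asarray(score.values, dtype=float), score.mask)


def run_stacks(stacks: dict[str, IndicatorStack],
               zones: ZoneMap | None = None,
               params: PipelineParams | None = None) -> PipelineResult:
    """Execute the full chain on in-memory per-epoch stacks."""
    params = params or PipelineParams()
    epochs = list(stacks)

    # cross-epoch pooled extremes: one physical value maps to one 0-10
    # score in every year, so per-cell change reflects real change
    extremes = pooled_extremes(stacks)
    standardized = {e: standardize_stack(stacks[e], params.category_tables,
                                         extremes)
                    for e in epochs}

    # one component count for every epoch: the smallest k that satisfies
    # the cumulative-contribution threshold in each epoch separately, so
    # the retained model is comparable across years
    pca_by_epoch: dict[str, spca.PcaResult] = {}
    for e in epochs:
        pca_by_epoch[e] = spca.fit_spca(standardized[e])
    _align_component_signs(pca_by_epoch)
    k_shared = max(
        spca.select_components(100 * pca_by_epoch[e].cumulative_rates,
                               params.spca_threshold_pct)
        for e in epochs)
    k_sel = {e: k_shared for e in epochs}
    evi_by_epoch = {e: vulnerability.compute_evi(pca_by_epoch[e], k_shared)
                    for e in epochs}

    svi_by_epoch = vulnerability.standardize_svi(evi_by_epoch)

    scheme = vulnerability.GradingScheme(breaks=params.grading_breaks)
    grades = {e: vulnerability.classify(svi_by_epoch[e], scheme) for e in epochs}
    cevi_overall = {e: grades[e].cevi for e in epochs}
    cevi_by_zone = None
    if zones is not None:
        cevi_by_zone = {e: vulnerability.compute_cevi(grades[e], zones)
                        for e in epochs}

    trend_surface = trend.fit_trend(evi_by_epoch)
    trend.classify_trend(trend_surface)

    metric_surfaces: dict[str, dict[str, Grid]] = {}
    global_rows = {}
    contributions: dict[str, contrib.ContributionTable] = {}
    simple_fits: dict[str, pd.DataFrame] = {}
    for e in epochs:
        class_grid = stacks[e].layers[params.categorical_layer_for_metrics]
        rec = landscape.metrics_of_grid(class_grid, params.connectivity)
        global_rows[e] = rec.as_dict()
        surfaces = landscape.moving_window(
            class_grid, window=params.window, stride=params.window_stride,
            connectivity=params.connectivity)
        metric_surfaces[e] = surfaces
        design = contrib.build_design_from_windows(
            surfaces, evi_by_epoch[e], window=params.window)
        contributions[e] = contrib.partial_contributions(design)
        simple_fits[e] = contrib.simple_regressions(design)

    return PipelineResult(
        standardized=standardized,
        pca=pca_by_epoch,
        k_selected=k_sel,
        evi=evi_by_epoch,
        svi=svi_by_epoch,
        grades=grades,
        cevi_overall=cevi_overall,
        cevi_by_zone=cevi_by_zone,
        trend=trend_surface,
        metric_surfaces=metric_surfaces,
        global_metrics=pd.DataFrame(global_rows).T,
        contributions=contributions,
        simple_fits=simple_fits,
    )


# ----------------------------------------------------------------------------
# configured, on-disk runs
# ----------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg


def _params_from_config(cfg: dict) -> PipelineParams:
    kw = {}
    if "spca_threshold" in cfg:
        kw["spca_threshold_pct"] = float(cfg["spca_threshold"])
    if "grading_breaks" in cfg:
        kw["grading_breaks"] = tuple(float(b) for b in cfg["grading_breaks"])
    if "window" in cfg:
        kw["window"] = int(cfg["window"])
    if "stride" in cfg:
        kw["window_stride"] = int(cfg["stride"])
    if "connectivity" in cfg:
        kw["connectivity"] = int(cfg["connectivity"])
    if "category_tables" in cfg:
        kw["category_tables"] = {
            name: {int(k): float(v) for k, v in table.items()}
            for name, table in cfg["category_tables"].items()}
    return PipelineParams(**kw)


def scenario_from_config(cfg: dict) -> ScenarioBundle:
    sc_kw = {}
    sc = cfg.get("scenario", {})
    for key in ("shape", "epochs"):
        if key in sc:
            sc_kw[key] = tuple(sc[key])
    for key in ("cell_size", "seed", "n_towns", "town_kernel_scale",
                "elevation_smoothness", "trend_positive_fraction",
                "trend_magnitude", "n_stations", "noise_sigma"):
        if key in sc:
            sc_kw[key] = sc[key]
    if "class_proportions" in sc:
        sc_kw["class_proportions"] = dict(sc["class_proportions"])
    if "seed" in cfg and "seed" not in sc_kw:
        sc_kw["seed"] = int(cfg["seed"])
    return generate_scenario(ScenarioConfig(**sc_kw))


def _load_stacks_from_dir(input_dir: Path, indicator_cfg: dict) -> dict[str, IndicatorStack]:
    from .grids import read_grid

    stacks: dict[str, IndicatorStack] = {}
    for edir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        stack = IndicatorStack(epoch=edir.name)
        for f in sorted(edir.iterdir()):
            if f.suffix.lower() not in (".asc", ".tif", ".tiff"):
                continue
            name = f.stem
            meta_cfg = indicator_cfg.get(name, {})
            meta = IndicatorMeta(meta_cfg.get("polarity", "positive"),
                                 meta_cfg.get("units", ""))
            stack.add(name, read_grid(f), meta)
        if len(stack):
            stacks[edir.name] = stack
    if not stacks:
        raise ValueError(f"no epoch directories with rasters under {input_dir}")
    return stacks


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  raster_format: str = "ascii-grid") -> Path:
    """Write tables and rasters plus a manifest with SHA-256 checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if raster_format == "ascii-grid" else ".tif"
    written: list[Path] = []

    def save_grid(grid: Grid, rel: str) -> None:
        path = out_dir / f"{rel}{ext}"
        path.parent.mkdir(parents=True, exist_ok=True)
        write_grid(grid, path, format=raster_format)
        written.append(path)

    def save_csv(df: pd.DataFrame, rel: str) -> None:
        path = out_dir / f"{rel}.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path)
        written.append(path)

    for e, res in result.pca.items():
        save_csv(spca.eigen_table(res), f"tables/eigen_{e}")
        save_csv(spca.loadings_frame(res, result.k_selected[e]),
                 f"tables/loadings_{e}")
        save_grid(result.evi[e], f"rasters/evi_{e}")
        save_grid(result.svi[e], f"rasters/svi_{e}")
        save_grid(result.grades[e].classes, f"rasters/grades_{e}")

    prop = pd.DataFrame({
        e: {vulnerability.GRADE_NAMES[c]: 100 * p
            for c, p in g.proportions.items()}
        for e, g in result.grades.items()
    }).T.fillna(0.0)
    save_csv(prop, "tables/class_proportions_pct")

    if result.cevi_by_zone is not None:
        save_csv(vulnerability.cevi_table(result.cevi_by_zone,
                                          result.cevi_overall), "tables/cevi")
    else:
        save_csv(pd.DataFrame({"cevi": result.cevi_overall}), "tables/cevi")

    save_grid(result.trend.slope, "rasters/trend_slope")
    if result.trend.classes is not None:
        save_grid(result.trend.classes, "rasters/trend_classes")
        pd.DataFrame({"break": result.trend.breaks}).to_csv(
            out_dir / "tables/trend_breaks.csv", index=False)
        written.append(out_dir / "tables/trend_breaks.csv")

    save_csv(result.global_metrics, "tables/landscape_metrics")
    for e, surfaces in result.metric_surfaces.items():
        for m, g in surfaces.items():
            save_grid(g, f"rasters/metric_{m}_{e}")
    for e, table in result.contributions.items():
        save_csv(table.frame(), f"tables/contribution_{e}")
        save_csv(result.simple_fits[e], f"tables/simple_regressions_{e}")

    manifest = {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(written)}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Run the configured pipeline and write outputs.

    ``config`` is a YAML path or an equivalent mapping.  ``mode: synthetic``
    generates the scenario inline; ``mode: files`` reads epoch directories of
    rasters from ``input_dir`` with per-indicator polarity metadata under
    ``indicators``.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    params = _params_from_config(cfg)
    mode = cfg.get("mode", "synthetic")

    zones = None
    if mode == "synthetic":
        bundle = scenario_from_config(cfg)
        stacks, zones = bundle.stacks, bundle.zones
    elif mode == "files":
        input_dir = Path(cfg["input_dir"])
        stacks = _load_stacks_from_dir(input_dir, cfg.get("indicators", {}))
        zones_path = cfg.get("zones")
        if zones_path:
            from .grids import load_zones_geojson
            template = next(iter(stacks.values())).reference()
            zones = load_zones_geojson(zones_path, template)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    result = run_stacks(stacks, zones=zones, params=params)

    out = out_dir or cfg.get("output_dir")
    if out is not None:
        write_outputs(result, out, cfg.get("raster_format", "ascii-grid"))
    return result
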