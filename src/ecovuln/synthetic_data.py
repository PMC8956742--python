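"""Synthetic mountainous-landscape scenarios for exercising the pipeline.

The generator emulates the statistical structure the vulnerability analysis
assumes: a forest-dominated land-use mosaic (91% forest by default) grown
from seeded nuclei, a smooth elevation field with derived slope and relief,
elevation-linked climate surfaces, town-centred population and disturbance
kernels, policy-zone masks, and a prescribed per-cell vulnerability trend
(a spatially clustered sign field with a configured positive fraction, 90%
by default) applied coherently to the disturbance-linked layers across
epochs.  Everything is reproducible from a single seed, and the generative
truth (class map, trend-sign map, town disturbance intensities) is returned
alongside the rasters so recovery can be scored.

Quantitative layers are built vulnerability-oriented on a 0-10 scale and
then flipped for negative-polarity indicators, so the pipeline's range
standardization is genuinely exercised (it has to undo the flip).  Drifting
layers are clipped to the scale, which pins the per-epoch extremes and
keeps their variance on the same footing as the static layers.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import Grid, IndicatorMeta, IndicatorStack, ZoneMap
from .indicators import StationSet, idw_interpolate

__all__ = [
    "ScenarioConfig",
    "TruthBundle",
    "ScenarioBundle",
    "RecoveryReport",
    "generate_scenario",
    "emit_scenario",
    "recovery_report",
]

#: Land-use category codes used by the generator.
LANDUSE_CODES = {1: "forest", 2: "grassland", 3: "cultivated",
                 4: "construction", 5: "water"}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a 200 x 200 cell (6 x 6 km at 30 m) mountainous
    mosaic observed over three epochs, 91% forest, eight towns, and 90% of
    cells on a rising vulnerability trajectory.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    seed: int = 0
    epochs: tuple[str, ...] = ("t1", "t2", "t3")
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "forest": 0.91, "grassland": 0.04, "cultivated": 0.02,
        "construction": 0.02, "water": 0.01,
    })
    n_towns: int = 8
    town_kernel_scale: float = 300.0       # metres; population kernel sigma
    town_disturbance: tuple[float, ...] | None = None  # per-town multipliers
    elevation_smoothness: float = 15.0     # cells; gaussian kernel sigma
    trend_positive_fraction: float = 0.90  # share of cells drifting upward
    trend_magnitude: float = 0.8           # 0-10 scale units per epoch step
    n_stations: int = 25
    noise_sigma: float = 0.15              # 0-10 scale units, iid per layer

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if not 0 < self.trend_positive_fraction <= 1:
            raise ValueError("trend_positive_fraction must be in (0, 1]")


@dataclass
class TruthBundle:
    """Generative ground truth for recovery scoring."""

    class_map: Grid                       # land-use codes (shared by epochs)
    trend_sign: Grid                      # +1 / -1 prescribed drift sign
    town_centers: list[tuple[int, int]]   # (row, col) of each town
    town_disturbance: list[float]         # per-town intensity multipliers
    config: ScenarioConfig


@dataclass
class ScenarioBundle:
    """Everything one scenario emits."""

    stacks: dict[str, IndicatorStack]     # per-epoch raw indicator stacks
    stations: StationSet                  # temperature monitoring points
    zones: ZoneMap                        # town zones
    truth: TruthBundle


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the generative truth."""

    positive_slope_fraction: float        # share of valid cells with K > 0
    sign_agreement: float                 # share where sign(K) == truth sign
    town_rank_correlation: float | None   # Spearman rho: disturbance vs CEVI
    ai_town_minus_forest: float | None    # AI contrast (negative expected)


# ----------------------------------------------------------------------------
# field helpers
# ----------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-range smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo)


def _scale01(f: np.ndarray) -> np.ndarray:
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def _grow_landuse(rng: np.random.Generator, shape, proportions: dict[str, float],
                  town_centers: list[tuple[int, int]],
                  elevation: np.ndarray | None = None) -> np.ndarray:
    """Quota-constrained multi-source region growing.

    Each class grows a patchy region from seeded nuclei until its cell quota
    is met; construction seeds sit at town centres and cultivated seeds next
    to them, which puts the disturbed classes where the towns are.  Frontier
    order is randomized (seeded), producing irregular patch boundaries.
    """
    nrows, ncols = shape
    n = nrows * ncols
    name_to_code = {v: k for k, v in LANDUSE_CODES.items()}

    quotas = {}
    for name, p in proportions.items():
        q = int(round(p * n))
        if p > 0 and q == 0:
            raise ValueError(
                f"class {name!r} proportion {p} yields zero cells on a "
                f"{nrows}x{ncols} grid")
        quotas[name_to_code[name]] = q
    # force exact total on the largest class
    largest = max(quotas, key=quotas.get)
    quotas[largest] += n - sum(quotas.values())

    seeds: list[tuple[int, int, int]] = []  # (code, r, c)
    code_constr = name_to_code["construction"]
    code_cult = name_to_code["cultivated"]
    for r, c in town_centers:
        seeds.append((code_constr, r, c))
        rr = min(nrows - 1, max(0, r + int(rng.integers(-6, 7))))
        cc = min(ncols - 1, max(0, c + int(rng.integers(-6, 7))))
        seeds.append((code_cult, rr, cc))
    for name, n_seeds in (("forest", 12), ("grassland", 6), ("water", 2)):
        code = name_to_code[name]
        for _ in range(n_seeds):
            if name == "water" and elevation is not None:
                # water collects in the valleys
                cr = rng.integers(0, nrows, 12)
                cc = rng.integers(0, ncols, 12)
                b = np.argmin(elevation[cr, cc])
                seeds.append((code, int(cr[b]), int(cc[b])))
            else:
                seeds.append((code, int(rng.integers(nrows)), int(rng.integers(ncols))))

    out = np.zeros(shape, dtype=int)
    remaining = dict(quotas)
    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for code, r, c in seeds:
        # seeds outrank every frontier cell so no class is starved
        heapq.heappush(heap, (-1.0 + float(rng.random()) * 1e-6, counter, r, c, code))
        counter += 1
    while heap:
        _, _, r, c, code = heapq.heappop(heap)
        if out[r, c] != 0 or remaining.get(code, 0) <= 0:
            continue
        out[r, c] = code
        remaining[code] -= 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and out[rr, cc] == 0:
                heapq.heappush(heap, (float(rng.random()), counter, rr, cc, code))
                counter += 1
    if (out == 0).any():  # quotas exhausted by blocked frontiers
        out[out == 0] = largest
    return out


def _kernel_field(shape, centers, amplitudes, sigma_cells: float) -> np.ndarray:
    """Sum of town-centred Gaussian kernels."""
    nrows, ncols = shape
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    out = np.zeros(shape)
    for (r, c), a in zip(centers, amplitudes):
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        out += a * np.exp(-0.5 * d2 / sigma_cells ** 2)
    return out


# ----------------------------------------------------------------------------
# scenario generation
# ----------------------------------------------------------------------------

def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Build the per-epoch indicator stacks, stations, zones, and truth."""
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    template = Grid(values=np.zeros(config.shape), cell_size=config.cell_size,
                    origin=(0.0, nrows * config.cell_size))

    # --- terrain first: town sites depend on it ---------------------------
    elevation = 400.0 + 2700.0 * _smooth_field(rng, config.shape,
                                               config.elevation_smoothness)

    # --- towns on a 2 x (n/2) zone lattice, one town per zone -------------
    # settlements sit in the valleys: each town takes the lowest-elevation
    # site among a handful of candidate cells in its zone
    n_towns = config.n_towns
    zrows, zcols = (2, (n_towns + 1) // 2) if n_towns > 1 else (1, 1)
    margin_r, margin_c = max(3, nrows // (zrows * 6)), max(3, ncols // (zcols * 6))
    town_centers: list[tuple[int, int]] = []
    zone_codes = np.zeros(config.shape, dtype=float)
    zone_names: dict[int, str] = {}
    code = 0
    for zr in range(zrows):
        for zc in range(zcols):
            if code >= n_towns:
                break
            code += 1
            r0, r1 = zr * nrows // zrows, (zr + 1) * nrows // zrows
            c0, c1 = zc * ncols // zcols, (zc + 1) * ncols // zcols
            zone_codes[r0:r1, c0:c1] = code
            zone_names[code] = f"town_{code}"
            cand_r = rng.integers(r0 + margin_r, r1 - margin_r, 12)
            cand_c = rng.integers(c0 + margin_c, c1 - margin_c, 12)
            best = np.argmin(elevation[cand_r, cand_c])
            town_centers.append((int(cand_r[best]), int(cand_c[best])))
    zones = ZoneMap(zones=template.with_values(zone_codes), names=zone_names)

    if config.town_disturbance is None:
        disturbance = list(np.round(rng.uniform(0.5, 2.0, n_towns), 3))
    else:
        if len(config.town_disturbance) != n_towns:
            raise ValueError("need one disturbance multiplier per town")
        disturbance = list(config.town_disturbance)

    # --- remaining static physical surfaces -------------------------------
    gy, gx = np.gradient(elevation, config.cell_size)
    slope_deg = np.degrees(np.arctan(np.hypot(gx, gy)))
    relief = (ndimage.maximum_filter(elevation, 3)
              - ndimage.minimum_filter(elevation, 3))

    class_map = _grow_landuse(rng, config.shape, config.class_proportions,
                              town_centers, elevation)
    water_mask = class_map == 5
    if water_mask.any():
        water_dist = ndimage.distance_transform_edt(~water_mask) * config.cell_size
    else:
        water_dist = np.full(config.shape, nrows * config.cell_size)
    # bounded influence measure: proximity to water matters within ~1 km
    water_influence = 10.0 * np.exp(-water_dist / 1000.0)

    # --- latent disturbance gradient and prescribed trend ------------------
    sigma_cells = config.town_kernel_scale / config.cell_size
    kernels = _kernel_field(config.shape, town_centers,
                            [8.0 * d for d in disturbance], sigma_cells)
    latent = _scale01(0.7 * _scale01(kernels)
                      + 0.3 * _smooth_field(rng, config.shape, 10.0))

    # finer scale than the static fields so the prescribed sign pattern is
    # spatially decorrelated from terrain and land use
    trend_field = ndimage.gaussian_filter(rng.standard_normal(config.shape),
                                          4.0, mode="nearest")
    thresh = np.quantile(trend_field, 1.0 - config.trend_positive_fraction)
    trend_sign = np.where(trend_field >= thresh, 1.0, -1.0)

    # --- stations for IDW (temperature, epoch-invariant) -------------------
    temperature = 25.0 - 0.006 * elevation \
        + 0.5 * ndimage.gaussian_filter(rng.standard_normal(config.shape), 8.0)
    st_rows = rng.integers(0, nrows, config.n_stations)
    st_cols = rng.integers(0, ncols, config.n_stations)
    x0, y0 = template.origin
    st_x = x0 + (st_cols + 0.5) * config.cell_size
    st_y = y0 - (st_rows + 0.5) * config.cell_size
    stations = StationSet(points=np.column_stack(
        [st_x, st_y, temperature[st_rows, st_cols]]))
    temp_grid = idw_interpolate(stations, template)

    precipitation = 900.0 + 0.4 * elevation \
        + 30.0 * ndimage.gaussian_filter(rng.standard_normal(config.shape), 6.0)

    # policy rasters: graded 0-10 protection strength, strongest where
    # elevation is high and towns are far (where parks actually sit)
    elev01 = _scale01(elevation)
    protect_park = 10.0 * _scale01(
        0.5 * elev01 + 0.4 * (1.0 - _scale01(kernels))
        + 0.1 * _smooth_field(rng, config.shape, 12.0))
    protect_reserve = 10.0 * _scale01(
        0.6 * (1.0 - _scale01(kernels))
        + 0.4 * _scale01(-water_dist))

    # --- vulnerability-oriented dynamic layers -----------------------------
    # each is built on a 0-10 scale and drifts additively by
    # trend_sign * magnitude per epoch step: the prescribed per-cell trend
    # is exactly two-valued, so it survives any epoch-common affine
    # transform (standardization, PCA centering) with its signs intact.
    # Clipping to the scale keeps the per-epoch extremes pinned and the
    # drifting layers' variance on the same footing as the static layers;
    # only the few cells that start within drift-reach of a scale boundary
    # flatten.
    def drifted(v0: np.ndarray, epoch_index: int) -> np.ndarray:
        return v0 + config.trend_magnitude * epoch_index * trend_sign

    def oriented(base01: np.ndarray, weight_latent: float,
                 drift: bool, epoch_index: int, noise: bool = True) -> np.ndarray:
        v = 10.0 * _scale01(weight_latent * latent + (1 - weight_latent) * base01)
        if drift:
            v = drifted(v, epoch_index)
        if noise and config.noise_sigma > 0:
            v = v + rng.normal(0.0, config.noise_sigma, v.shape)
        return np.clip(v, 0.0, 10.0)

    veg_base = _scale01(0.5 * (class_map == 1)
                        + 0.2 * _smooth_field(rng, config.shape, 8.0))

    # per-layer base structure is drawn once: across epochs only the
    # prescribed drift and iid measurement noise change
    iw_base = _smooth_field(rng, config.shape, 6.0)
    ds_base = _smooth_field(rng, config.shape, 6.0)
    wq_base = _smooth_field(rng, config.shape, 6.0)
    fiscal_base = _smooth_field(rng, config.shape, 10.0)

    stacks: dict[str, IndicatorStack] = {}
    for e, epoch in enumerate(config.epochs):
        stack = IndicatorStack(epoch=epoch)
        pos = IndicatorMeta("positive")
        neg = IndicatorMeta("negative")
        cat = IndicatorMeta("categorical")

        pop = np.clip(drifted(_scale01(kernels) * 10.0, e), 0.0, 10.0)
        stack.add("population_density", template.with_values(pop), pos)

        tour = oriented(_scale01(kernels), 0.85, drift=True, epoch_index=e,
                        noise=False)
        stack.add("tourist_reception", template.with_values(tour), pos)

        stack.add("industrial_wastewater", template.with_values(
            oriented(iw_base, 0.85, True, e)), pos)
        stack.add("domestic_sewage", template.with_values(
            oriented(ds_base, 0.85, True, e)), pos)

        stack.add("land_use", template.with_values(class_map.astype(float)), cat)
        stack.add("slope", template.with_values(slope_deg), pos)
        stack.add("relief", template.with_values(relief), pos)

        # vegetation: high coverage = low vulnerability -> negative polarity,
        # so the raw layer is the flipped oriented surface
        veg_vuln = oriented(1.0 - veg_base, 0.75, drift=True, epoch_index=e)
        stack.add("vegetation_coverage",
                  template.with_values((10.0 - veg_vuln) / 10.0), neg)

        stack.add("temperature", temp_grid.copy(), pos)
        stack.add("precipitation", template.with_values(precipitation), neg)
        stack.add("water_influence", template.with_values(water_influence), pos)

        wq_vuln = oriented(wq_base, 0.85, True, e)
        stack.add("water_quality", template.with_values(10.0 - wq_vuln), neg)

        fiscal = oriented(fiscal_base, 0.3, drift=False, epoch_index=e)
        stack.add("fiscal_revenue", template.with_values(10.0 - fiscal), neg)

        # protection strength is negative-polarity: stronger protection,
        # lower vulnerability
        stack.add("national_park_policy",
                  template.with_values(protect_park), neg)
        stack.add("nature_reserve_policy",
                  template.with_values(protect_reserve), neg)
        stacks[epoch] = stack

    truth = TruthBundle(
        class_map=template.with_values(class_map.astype(float)),
        trend_sign=template.with_values(trend_sign),
        town_centers=town_centers,
        town_disturbance=disturbance,
        config=config,
    )
    return ScenarioBundle(stacks=stacks, stations=stations, zones=zones,
                          truth=truth)


#: Categorical score tables the pipeline applies to the generator's
#: categorical layers: the five-class land-use assignment (forest and water
#: low, construction high).
CATEGORY_TABLES = {
    "land_use": {1: 2.0, 2: 4.0, 3: 6.0, 4: 8.0, 5: 2.0},
}


# ----------------------------------------------------------------------------
# on-disk emission
# ----------------------------------------------------------------------------

def emit_scenario(bundle: ScenarioBundle, out_dir: str | Path,
                  raster_format: str = "ascii-grid") -> Path:
    """Write the scenario in the layout the pipeline consumes.

    One raster per indicator per epoch, a stations CSV, a zones GeoJSON
    (rectangular town zones), and ``truth.json`` with the generative
    parameters.
    """
    from .grids import write_grid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if raster_format == "ascii-grid" else ".tif"

    for epoch, stack in bundle.stacks.items():
        edir = out_dir / epoch
        edir.mkdir(exist_ok=True)
        for name, grid in stack:
            write_grid(grid, edir / f"{name}{ext}", format=raster_format)

    with open(out_dir / "stations.csv", "w") as fh:
        fh.write("x,y,value\n")
        for x, y, v in bundle.stations.points:
            fh.write(f"{x:.6g},{y:.6g},{v:.6g}\n")

    # zone rectangles back to polygons
    zones = bundle.zones
    zvals = np.asarray(zones.zones.values)
    cell = zones.zones.cell_size
    x0, y0 = zones.zones.origin
    features = []
    for zcode in zones.codes():
        rows, cols = np.nonzero(zvals == zcode)
        r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
        xmin, xmax = x0 + c0 * cell, x0 + (c1 + 1) * cell
        ymax, ymin = y0 - r0 * cell, y0 - (r1 + 1) * cell
        ring = [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax],
                [xmin, ymin]]
        features.append({
            "type": "Feature",
            "properties": {"code": int(zcode), "name": zones.names[zcode]},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    with open(out_dir / "zones.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    truth = bundle.truth
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({
            "town_centers": [list(tc) for tc in truth.town_centers],
            "town_disturbance": truth.town_disturbance,
            "trend_positive_fraction": truth.config.trend_positive_fraction,
            "seed": truth.config.seed,
            "shape": list(truth.config.shape),
            "epochs": list(truth.config.epochs),
        }, fh, indent=1)
    from .grids import write_grid as _wg
    _wg(truth.trend_sign, out_dir / f"truth_trend_sign{ext}", format=raster_format)
    _wg(truth.class_map, out_dir / f"truth_class_map{ext}", format=raster_format)
    return out_dir


# ----------------------------------------------------------------------------
# recovery scoring
# ----------------------------------------------------------------------------

def recovery_report(truth: TruthBundle, trend_slope: Grid,
                    cevi_by_zone: dict[str, float] | None = None,
                    ai_surface: Grid | None = None) -> RecoveryReport:
    """Score pipeline outputs against the generative truth.

    Reports the positive-slope fraction and the per-cell sign agreement of
    the fitted trend, the Spearman rank correlation between town disturbance
    intensity and town CEVI, and the AI contrast between town neighbourhoods
    and deep forest (expected negative: towns fragment the mosaic).
    """
    if trend_slope.shape != truth.trend_sign.shape:
        raise ValueError("trend surface geometry does not match the truth")

    mask = trend_slope.mask & truth.trend_sign.mask
    k = np.asarray(trend_slope.values)[mask]
    sign_true = np.asarray(truth.trend_sign.values)[mask]
    positive_fraction = float((k > 0).mean())
    agreement = float((np.sign(k) == sign_true).mean())

    rho = None
    if cevi_by_zone is not None:
        from scipy import stats
        names = sorted(cevi_by_zone)
        idx = [int(n.rsplit("_", 1)[1]) - 1 for n in names]
        d = [truth.town_disturbance[i] for i in idx]
        c = [cevi_by_zone[n] for n in names]
        rho = float(stats.spearmanr(d, c).statistic)

    ai_contrast = None
    if ai_surface is not None:
        vals = np.asarray(ai_surface.values)
        m = ai_surface.mask
        nrows, ncols = ai_surface.shape
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        near = np.zeros(ai_surface.shape, dtype=bool)
        radius = truth.config.town_kernel_scale / truth.config.cell_size * 2
        for r, c in truth.town_centers:
            near |= (rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2
        forest = (np.asarray(truth.class_map.values) == 1) & ~near
        if (near & m).any() and (forest & m).any():
            ai_contrast = float(vals[near & m].mean() - vals[forest & m].mean())

    return RecoveryReport(
        positive_slope_fraction=positive_fraction,
        sign_agreement=agreement,
        town_rank_correlation=rho,
        ai_town_minus_forest=ai_contrast,
    )
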