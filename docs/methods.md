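# Methods

## The model

The package assesses ecological vulnerability on co-registered raster
stacks following the exposure–sensitivity–adaptability decomposition of
vulnerability scoring: external stress on the ecosystem (population
pressure, tourism, wastewater), its propensity to be harmed (terrain,
climate, vegetation, land use, water environment), and its capacity to
recover (economic capacity, protection policy).  Each indicator is mapped
onto a common 0–10 scale on which larger always means more vulnerable:

* positive polarity: `Y = 10 (X − Xmin) / (Xmax − Xmin)`
* negative polarity: `Y = 10 (Xmax − X) / (Xmax − Xmin)`
* categorical indicators: table lookup (land use scores forest 2,
  grassland 4, cultivated 6, construction 8, water 2)

Extremes default to the per-epoch valid-cell range; the pipeline passes
pooled cross-epoch extremes instead, so one physical value maps to one
score in every year and per-cell change across epochs reflects real change
rather than a moving yardstick.  Both behaviours are available through the
`extremes` override of `standardize`/`standardize_stack`.

The standardized stack of one epoch is reduced by PCA on its covariance
matrix (the layers share the 0–10 scale by construction, so no further
rescaling; mean-centering only).  With eigenvalues `λ₁ ≥ λ₂ ≥ …`, the
contribution rate of component *i* is `rᵢ = λᵢ / Σλ`, components are
retained until the cumulative rate reaches 90%, and the ecological
vulnerability index of a cell is the rate-weighted sum of its retained
component scores:

    EVI = r₁Y₁ + r₂Y₂ + … + r_kY_k

with the `rᵢ` taken as computed (not renormalized over the retained k).
Cross-epoch comparability comes from pooling the extremes of all epochs'
EVI surfaces:

    SVI = 10 (EVI − EVImin) / (EVImax − EVImin)   ∈ [0, 10]

SVI is cut into five equal-width grades (breaks 2, 4, 6, 8; lower-closed,
top class closed at 10): I micro, II mild, III moderate, IV severe,
V extreme.  The comprehensive index of a region is the area-weighted mean
grade `CEVI = Σ Lᵢ·Aᵢ/S ∈ [1, 5]`, computed for the whole landscape and
per zone (zonal membership by cell center).

Temporal change is the per-cell least-squares slope of EVI against the
1-based epoch index,

    K = (n Σ i·EVIᵢ − Σi · ΣEVIᵢ) / (n Σi² − (Σi)²),

positive where vulnerability rises.  The slope surface is classified into
five change levels by Fisher–Jenks natural breaks.  Landscape structure is
summarized by five landscape-level metrics (NP, LPI, AI, DIVISION, SHDI)
computed globally and in moving windows, and their joint influence on EVI
is decomposed by leave-one-out partial regression: with full-model
regression sum of squares `U` and `Uᵢ` after removing metric *i*,
`Pᵢ = U − Uᵢ ≥ 0` and the contribution rate is `Sᵢ = 100·Pᵢ/ΣPⱼ`.

## Conventions the equations do not fix

Several choices are under-determined by the formulas above; the package
fixes them as follows.

**Component orientation.**  Eigenvector sign is arbitrary.  A component
whose loadings share a direction (|Σ loadings| ≥ 0.25·√p) is a common-mode
component and is oriented *with* the vulnerability scale (positive loading
sum), which keeps "larger EVI = more vulnerable" true by construction.  A
contrast component (loading sum near zero) carries no vulnerability
orientation of its own and is oriented by its largest-magnitude loading,
the stable structural feature of such a vector.  When several epochs are
analyzed together, the pipeline additionally aligns every epoch's
components against the first epoch (flip on negative loading dot product),
the usual longitudinal-PCA sign alignment — without it a component can
flip between years and corrupt every cross-epoch quantity.

**One component count for all epochs.**  The ≥90% rule is evaluated per
epoch and the maximum of the per-epoch counts is used for every epoch, so
the retained model is the same object in every year.

**Grading boundaries.**  Lower-closed intervals ([2, 4) etc.) with the top
class closed at 10, so the pooled maximum belongs to grade V.  CEVI tables
round half-up to 2 decimals.

**Jenks.**  Exact dynamic programme over sorted values (O(k·n²)); among
equal-cost partitions the smallest first break wins.  Inputs longer than
`max_n = 4000` are reduced to a deterministic sample at evenly spaced ranks
of the sorted values before the programme runs — the standard large-raster
treatment; the breaks are then applied to the full surface.

**Landscape metrics.**  The canonical landscape-level definitions: NP is
the patch count under 8-neighbour connectivity (configurable to 4); LPI is
the largest patch's percentage of landscape area; SHDI is `−Σ p_c ln p_c`
over class area shares; DIVISION is `1 − Σ (a/A)²` over patches; AI is
`100·Σ_c P_c·g_cc/max g_cc` with `g_cc` the single-count rook like-adjacency
count and `max g_cc` the largest-integer-square packing bound
(`2s(s−1)` for a perfect square `s² = m`, plus `2r−1` or `2r−2` for the
remainder `r = m − s²` depending on whether `r ≤ s`).  A single-cell class
contributes zero aggregation.  Moving windows that leave the grid are
masked, never padded — padding would fabricate adjacencies.

**Contribution sampling.**  The regression pairs each evaluated
moving-window center (already strided) with the mean EVI inside that
window's footprint.  Reduced models keep the intercept so the models nest
and every `Pᵢ` is non-negative.  Significance reporting is descriptive; no
multiple-testing correction is applied.

**IDW.**  `w = d^(−power)` over the k nearest stations (defaults power 2,
k 12; both exposed); a cell whose center coincides with a station takes the
station value; nearest-neighbour ties break by station input order.

**Degenerate inputs.**  Constant layers warn and yield a zero-variance
component; a degenerate standardization range (`Xmax == Xmin`), an empty
station set, fewer valid cells than indicators, exact design collinearity,
and fewer distinct values than classes are all errors.  All multi-layer
computations run on the intersection of the layer masks.

## The synthetic scenario generator

`synthetic_data.generate_scenario` emulates the statistical structure of a
mountainous protected-area landscape so the whole chain can run and be
validated without any external data:

* a land-use mosaic grown by quota-constrained multi-source region growing
  (91% forest by default; construction seeded at town centers, water in
  valleys), giving realistic patch structure for the metrics;
* a smooth elevation field (Gaussian-filtered noise, σ = 15 cells) with
  derived slope and relief; towns sit at the lowest-elevation candidate
  site of their zone, as real settlements do;
* elevation-linked climate surfaces, a station set with IDW-interpolated
  temperature, a bounded water-influence surface `10·exp(−d/1 km)`;
* town-centered Gaussian disturbance kernels (σ = 300 m) with per-town
  intensity multipliers, driving population, tourism, wastewater and the
  latent disturbance gradient shared by those layers;
* graded protection-strength surfaces strongest at high elevation far from
  towns (negative polarity: protection lowers vulnerability);
* a prescribed per-cell trend: a spatially clustered sign field (σ = 4
  cells, finer than the static fields so it is decorrelated from them) with
  a configured positive fraction (default 90%), applied as an additive
  ±0.8 (0–10-scale units) per epoch step to the disturbance-linked layers,
  clipped to the scale.  The two-valued additive drift survives
  standardization and PCA centering with its signs intact; clipping keeps
  per-epoch extremes pinned and the drifting layers' variance on the same
  footing as the static layers.  iid noise (σ = 0.15) is added per layer
  per epoch.

Everything is reproducible from one seed, and the generative truth (class
map, trend-sign map, town intensities) is returned for recovery scoring
(`recovery_report`): fitted-slope sign agreement, Spearman rank correlation
of town CEVI against town disturbance intensity, and the aggregation
contrast between town neighbourhoods and forest interior.

What the generator does **not** emulate: spatial autocorrelation of
measurement error, mixed-pixel effects at class boundaries, land-use change
between epochs (the mosaic is static; change is carried by the continuous
layers), anisotropic terrain, or calibration to any real geography.
Passing tests therefore demonstrate that the pipeline recovers structure
*of the kind it assumes*, not that the indicator system is adequate for a
particular real landscape.

## Known limitations

* **Per-epoch re-weighting bias in the trend.**  Because each epoch is
  decomposed separately, sustained one-sided drift inflates the leading
  eigenvalue over time and with it the EVI amplitude `r₁·√λ₁`; cells below
  the landscape mean are pushed further down in later epochs, which reads
  as a spurious negative trend for weak-trend background cells.  On the
  default scenario the fitted positive-slope fraction therefore runs a few
  points below the prescribed fraction (the acceptance suite measures it);
  holding the first epoch's weights fixed recovers the prescribed signs
  almost exactly, isolating the re-weighting — not the slope estimator —
  as the source.  This is a property of the published index construction
  and is left intact.
* Rotated factor solutions are out of scope; loadings are reported for the
  retained unrotated components.
* Reprojection between coordinate systems is out of scope; the `crs_tag`
  is carried through I/O but never interpreted, and all layers must share
  one geometry.
* The Jenks rank-sampling cap makes breaks on very large rasters exact for
  the sample, not the full multiset; with `max_n = 4000` the deviation is
  far below the class widths in practice.

## Problem sizes

The default end-to-end scenario is 200 × 200 cells × ~15 indicators × 3
epochs, with 33-cell metric windows on a 4-cell stride; the full chain runs
in a few seconds on one CPU.  Unit and property tests run on grids between
2 × 2 and 20 × 20, where exhaustive and brute-force oracles are feasible.
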