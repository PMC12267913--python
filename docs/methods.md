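# Methods

This note documents the models, parameter choices, and numerical details
behind `canopyflux`, and what the synthetic validation does and does not
demonstrate about real airborne-laser-scanning (ALS) data.

## Rasters and units

All layers are single-band, north-up, square-pixel grids (`RasterGrid`)
with an explicit nodata sentinel; heights are meters above ground
(float32), terrain meters above sea level, class maps uint8 with
nodata 255. GeoTIFF I/O is implemented on `tifffile` with the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA), which is
sufficient because the pipeline never reprojects: both CHM epochs must be
exactly co-registered, and `align_pair` fails with an offset report
otherwise. Survey dates are converted to decimal years as
day-count / 365.25 (the reference ALS pair, Oct 2014 to Feb 2020, gives
5.34 yr).

Pixels with pulse density < 2 m⁻² or scan angle > 20° are masked when
quality rasters are supplied; absent rasters mean "assume passed", since
synthetic data have no acquisition artifacts. Analysis cells are 100 × 100
m (1 ha): small enough to keep topography and forest type homogeneous,
large enough to contain the largest canopy events. Cells with > 5%
missing pixels, without a single forest type at ≥ 75% cover, or partially
outside the raster are excluded.

## Gap definition and change classes

Gap pixels satisfy `h < cutoff` **strictly**. The fixed cutoff is 10 m and
the minimum area 25 m²; the boundary semantics (strict at 10, `≥` at
25 m², drop strictly `> 5` m) are pinned by tests because real pipelines
disagree exactly at these edges. Connectivity is 8-neighbor by default
(diagonally touching openings merge), with 4-neighbor available — on
continuous height data the choice is measure-zero at the cutoff but not
for component merging, so it is a parameter, not a guess. In relative mode
the cutoff is `relative_fraction × reference_height` per forest type,
with the reference the type's mean canopy height.

Change classification is resolved per pixel from the epoch-wise
*qualifying-gap* sets, so the expansion fringe of an old gap counts as
formation even when the newly opened sliver alone is under 25 m²:
qualification is per gap object and per epoch. "Recovered" (closure)
means no longer belonging to any qualifying second-epoch gap, which
covers both regrowth above the cutoff and shrinkage of a component below
the minimum area; this keeps the five classes an exact partition of the
valid pixels. Disturbance patches are connected components of
`Δh < −5 m` pixels outside both gap sets, filtered at 25 m². Persistent
gaps losing height remain in the gains group; that convention (and the
possibility of negative gains) is preserved and exercised by the tests.

Per-cell height rates are reported two ways: the class-conditional mean
(`hrate_*`, m yr⁻¹ — the rate *within* that process, e.g. ~2 m yr⁻¹ in
closing gaps vs ~0.1–0.3 m yr⁻¹ in intact canopy) and the cell-normalized
group rates (`gains_height`, `losses_height`, `net_height`). Volume rates
divide by the cell's nominal area so a 1-ha cell reads directly in
m³ ha⁻¹ yr⁻¹; the signed class volumes always sum to the cell's total
Δh volume (conservation is asserted to 1e-6 relative).

## Terrain derivatives

Slope uses Horn's 3×3 kernel on the DTM aggregated to 10 m (block mean;
any nodata poisons its block). TWI is computed at 25 m: mean-resample the
10-m DTM (source pixels assigned by center, handling the non-integer 10→25
ratio), priority-flood fill with an epsilon gradient (1e-5) so no flats
stall, route with single-direction D8 (ties broken in fixed
E, SE, S, SW, W, NW, N, NE order; off-grid neighbors are never targets, a
cell with no lower in-grid neighbor is an outlet), then
`TWI = ln(a / max(tan β, 1e-3))` with specific catchment area
`a = accumulated area / cell width`. These are the simplest reproducible
choices; multiple-flow-direction routing would smear accumulation and is
out of scope. Flow accumulation conserves area exactly (the sum over
outlets equals the landscape area), TWI and slope are invariant under
elevation translation, and on the synthetic landscape TWI and slope are
negatively correlated across 1-ha cells, as on real dissected terrain.

## Structural metrics

H_mean is the mean over all valid pixels (not only canopy pixels — the
distinction matters in gap-rich cells and is the documented convention
here). H_max is the 98th percentile with linear interpolation between
order statistics (pinned for reproducibility). H_cv is the quantile ratio
`(q95 − q5)/(q95 + q5)`: outlier-insensitive and bounded in [0, 1) for
positive heights. The exact robust-CV formula is injectable
(`cv_statistic=`) so an alternative estimator with the same contract can
be swapped in. GF10 is the fraction of valid pixels below the gap cutoff.

## Statistical layer

- ANOVA across forest types uses `scipy.stats.f_oneway`, with Tukey HSD
  (statsmodels) for the family-wise pairwise comparisons.
- Univariate models fit `y ~ x × type` with per-type intercepts and
  slopes (types with < 3 records get no slope), plus the pooled fit and
  pooled Pearson r.
- Multiple models are OLS on z-scored predictors; the naive R² is
  in-sample and no effect-size comparison between correlated predictors
  is offered.
- Volume losses are made absolute and log(x + 1)-transformed before any
  fit; the 1 m³ ha⁻¹ yr⁻¹ offset (recorded in the code as
  `LOSS_LOG_OFFSET`) keeps zero-loss cells defined and is negligible at
  the scale of the rates.
- The spatial cross-validation first fits the model, estimates the
  residual autocorrelation range from a Matheron semivariogram (bin width
  = cell size, max lag = half the landscape diameter) with a spherical
  model fitted by least squares (multi-start over candidate ranges, since
  the objective has nugget-absorbing local minima; a vanishing partial
  sill reports range 0), then refits leave-one-out excluding all training
  cells within that range of the held-out cell. Cells whose buffer leaves
  fewer than p + 2 training rows are skipped and counted. With
  autocorrelated residuals the buffered R² is systematically below the
  naive one; with white-noise residuals the two coincide.

## Synthetic landscape

The simulator generates the study conditions the analysis assumes, with
per-pixel truth labels as the validation oracle.

- **Terrain**: base 50 m + 200 m ridge sinusoid (wavelength 300 m) + a
  small cross-valley tilt (0.01) so valleys drain, + correlated noise
  (sd 3 m, range 60 m), clipped to [50, 250] m.
- **Forest types** by elevation band (alluvial < sandstone < kerangas);
  thresholds default to the DTM terciles so the three zones have equal
  area.
- **Canopy**: per-type Gaussian random fields (spectral synthesis with an
  exponential-decay spectrum; the range parameter controls the spectrum's
  decay scale, not a variogram range) with means 42 / 34 / 26 m and sd
  3 / 2.5 / 2 m; initial gap disks are injected at 1.2 / 0.7 / 0.5 ha⁻¹
  with floors 1–7 m.
- **Dynamics over the 5.34-yr interval**: intact growth 0.30 / 0.18 /
  0.12 m yr⁻¹ (growth may be set negative to exercise negative gains);
  closure of a 40% random subset of initial gaps (raised to 13–17 m);
  bounded drift on persisting gaps (clamped to 0.5–7.5 m); Poisson
  formation disks at 1.2 / 0.7 / 0.5 ha⁻¹ (50–150 m², floors 1–7 m);
  Poisson disturbance patches at 1.0 / 0.6 / 0.33 ha⁻¹ (40–90 m²)
  flattened to a 13–14 m floor, accepted only where the pre-event canopy
  keeps every drop above 7.3 m; finally Gaussian measurement noise
  (default sd 0.25 m) on the second epoch only — the first epoch is the
  constructed reference.
- **Margins**: by default every simulated magnitude sits ≥ 2 m away from
  the corresponding detection threshold, so a correct classifier must
  reproduce the truth *exactly* in the noise-free case, and 0.25-m noise
  cannot plausibly cross any boundary. `threshold_margin = 0` switches to
  the boundary-sensitivity regime.
- **Events are disks** placed by rejection with a one-pixel separation
  buffer. Real gaps are irregular, but no implemented statistic depends
  on shape beyond area and connectivity, and disks keep truth labels
  unambiguous.

`expected_type_rates` computes the per-type volume gain/loss rates implied
by a configuration analytically (expectations of the uniform event
distributions). The defaults were chosen so the configured
alluvial:kerangas loss ratio is ≈ 4.7 and the gain ratio ≈ 2.5, with
alluvial > sandstone > kerangas throughout — the design point of the
validation. Realized rates fluctuate per seed (Poisson event counts: a
25-ha landscape holds only ~10–40 events per type), so rate-recovery
checks pool the event registries over 20 seeds of a 100-ha landscape,
where the pooled sampling CV is a few percent.

All randomness derives from a single seed through per-stage
`SeedSequence` streams; the full bundle is bit-reproducible.

## Problem sizes used in validation

Partition/conservation checks run on 100 seeded 2.56-ha landscapes; truth
recovery on the default 25-ha landscape; rate recovery on twenty 100-ha
landscapes; the spatial-CV calibration on 20×20 grids of 1-ha cells; the
ANOVA calibration on 10 000 null replicates of 3 × 30 observations. These
sizes give sampling errors comfortably inside the asserted tolerances
while keeping the whole suite fast on a single CPU.

## What the synthetic validation does not show

The simulator emulates the *structure* of repeat-ALS data, not its
physics: no point-cloud processing, no CHM-algorithm or ground-
classification sensitivity, no co-registration error, no view-angle or
density-dependent height bias, and measurement noise is i.i.d. Gaussian
rather than spatially structured. Passing the truth-recovery tests
demonstrates that the implementation applies its own definitions exactly;
it does not validate the 10 m / 25 m² / 5 m thresholds as estimators of
ecological disturbance in real forests, where threshold sensitivity
should be explored with the alternative definitions (relative cutoff,
10 m² area floor) the gap module exposes.
Lateral crown expansion vs vertical regrowth within gap closure is not
decomposed, and no biomass conversion is attempted.

## Known limitations

- D8 routing concentrates flow on a single path; TWI values on convergent
  synthetic terrain are coarser than multiple-flow-direction estimates.
- The spherical variogram range on a single realization is a noisy
  estimator (±30% at ~400 cells); the CV buffer inherits that noise.
- `fill_pits` treats interior nodata holes as drains while flow routing
  avoids them; with large nodata areas the TWI near hole edges is
  approximate.
- The purity rule (≥ 75% single type) can discard most cells when forest
  types band at scales close to the cell size; widen the terrain
  wavelength (as in the README demo) or shrink cells for such layouts.
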