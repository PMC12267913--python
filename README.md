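# canopyflux

Canopy gap dynamics from repeat airborne-laser-scanning canopy height
models (CHMs).

Old-growth tropical forest landscapes can turn over at very different
rates within a few hundred meters, as soils and topography shift the
balance between gap formation and canopy regrowth. `canopyflux` implements
a complete, tested pipeline for quantifying that variation from two
co-registered CHM epochs: it detects canopy gaps, partitions per-pixel
height change into five dynamic processes, accounts per-hectare height and
volume fluxes, derives the topographic covariates that predict them, and
fits spatially cross-validated regressions — plus a synthetic landscape
simulator with per-pixel truth labels so every stage can be validated
end to end without any field data.

It is aimed at forest ecologists and remote-sensing analysts working with
repeat lidar over structurally heterogeneous forests (e.g. alluvial /
sandstone / kerangas mosaics on tropical soil gradients).

## The model

**Gaps.** A canopy gap is a connected region (8-neighbor by default) of
CHM pixels with height `h < 10 m` and total area `≥ 25 m²` — roughly one
canopy tree crown. A forest-type-relative variant (`h < 0.5 · H̄_type`)
and a 10 m² area floor are available for sensitivity analyses.

**Five-class change partition.** Given gap sets G₁, G₂ at the two epochs
and the height difference Δh = CHM₂ − CHM₁, every valid pixel gets exactly
one label:

| class | rule |
|---|---|
| gap formation | ∉ G₁ ∧ ∈ G₂ |
| canopy disturbance | connected Δh < −5 m patch ≥ 25 m², outside G₁ ∪ G₂ |
| gap persistence | ∈ G₁ ∧ ∈ G₂ |
| gap closure | ∈ G₁ ∧ ∉ G₂ |
| intact canopy | everything else |

Formation + disturbance are **losses**; the other three are **gains**
(gains can be negative when intact or persistent-gap areas sink). Per 1-ha
cell the pipeline reports each class's area fraction, class-conditional
height rate (m yr⁻¹), and signed volume rate
`Σ Δh · pixel_area / area_ha / Δt` (m³ ha⁻¹ yr⁻¹), with
`net = gains − losses` exactly conserving the total Δh volume.

**Covariates.** Per cell: mean elevation, Horn slope on the 10-m DTM,
topographic wetness index `TWI = ln(a / tan β)` at 25 m (D8 flow routing
on the pit-filled DTM), and canopy structure H_mean, H_max (98th
percentile), robust H_cv = (q95 − q5)/(q95 + q5), and GF10 (fraction of
pixels < 10 m). Cells with > 5% missing pixels or without a single forest
type covering ≥ 75% are excluded.

**Statistics.** One-way ANOVA across forest types with Tukey HSD;
univariate regressions with a forest-type interaction; multiple OLS on
standardized predictors; and leave-one-out cross-validation with a spatial
exclusion buffer equal to the range of a spherical semivariogram fitted to
the model residuals — the honest R² under spatial autocorrelation. Volume
losses are |·| then log(x+1)-transformed before fitting.

## Worked example

Simulate a 100-ha landscape with three elevation-banded forest types and
run the full pipeline:

```bash
cat > demo.json <<'JSON'
{"landscape": {"extent": [1000.0, 1000.0], "seed": 42,
               "terrain": {"ridge_wavelength": 2000.0}},
 "stats": {"response": "gains_volume",
           "predictors": ["elevation", "twi", "h_max", "h_cv"]}}
JSON
canopyflux run --config demo.json --out-dir demo/
```

`demo/dynamics.csv` holds one row per valid 1-ha cell. The first rows look
like:

```
 cell_row  cell_col  forest_type  gains_volume  losses_volume  net_volume  h_max  gf10  twi
        0         0            1       2909.91        1596.54     1313.37  47.91  0.01 6.70
        0         1            1       2705.78         330.54     2375.24  46.93  0.03 6.60
        0         2            2       1878.79         615.30     1263.49  39.88  0.02 5.99
        0         4            3       1190.97         202.60      988.38  30.69  0.00 7.31
```

Forest type 1 (alluvial, tall canopy on the valley floor) turns over
fastest; type 3 (kerangas, short canopy on the hilltops) slowest — the
per-type means of this run are gains 2957 / 1830 / 1245 and losses
1277 / 562 / 238 m³ ha⁻¹ yr⁻¹ for types 1 / 2 / 3. `demo/stats.json`
reports the gains regression over the 72 valid cells:

```
{"formula": "gains_volume ~ elevation + twi + h_max + h_cv",
 "n": 72, "r2_naive": 0.973,
 "autocorrelation_range_m": 650.0, "r2_spatial": 0.906}
```

i.e. a residual autocorrelation range of 650 m, and a buffered
cross-validated R² of 0.91 against the naive in-sample 0.97.

Python API equivalents live in `canopyflux.pipeline.build_cell_records`,
`canopyflux.gap_detection.detect_gaps`,
`canopyflux.change_classification.classify_change`, and
`canopyflux.landscape_stats.spatial_loo_cv`.

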