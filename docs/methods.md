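# Methods

`wetlandval` assesses a reclaimed coal-mining subsidence area along two
axes: what the land itself is now worth ecologically (ecosystem-service
valuation and ecological storage), and what the restoration is worth to the
land around it (a land-price spillover model on kriged price surfaces).
This note records the models, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Ecosystem-service valuation

The valuation is a benefit transfer: each land-cover class i with area A_i
(hm²) carries a per-hectare-per-year value coefficient VC_i (yuan/hm²/a),
and

    ESV = Σ_i A_i · VC_i.

The builtin coefficient scheme targets a North China Plain mining area:
equivalent-value coefficients for cultivated land (6,114.3), woodland
(19,334), grassland (6,406.5) and natural water (40,676.4), mining-city
corrections that make the industry/transportation (−5,372.1) and urban
(−1,760.5) classes net costs, and a subsided-water column (10,135.9) that
discounts the natural-water services degraded by mine-water pollution and
zeroes soil formation and recreation outright. Reporting is in 万元
(10⁴ yuan) because the per-class tables are only interpretable in that
unit; converters to yuan are explicit.

Change rates use the plain signed ratio (after − before)/before × 100. With
negative-valued classes this means a shrinking cost prints as a negative
rate (the burden decreased), which is the convention under which published
ESV change tables for such areas are internally consistent. A zero base is
flagged undefined rather than coerced.

The ecological storage state condenses the valuation into a density,

    ESS = (1/h) · ΣESV_i / ΣA_i        (万元·hm⁻²),

with h = 1 for a single year's state. Conversion between two states is
reported as the ESS difference and its *linear* annualization
(difference/years × 100); the linear rather than geometric definition is
what reproduces published conversion-percent tables.

Areas come purely from cell counts (count × cell² / 10⁴), never from
polygonization, so any class area is exact and the tabulation is invariant
to layout. Percentages print at two decimals, round-half-up, matching
table conventions. Nodata cells are excluded from all accounting.

## Geostatistics

Land prices are point samples; surfaces come from ordinary kriging. The
chain is deliberately explicit rather than delegated, because every
downstream number inherits its assumptions:

* **Screening.** Shapiro–Wilk normality (advisory; a failing sample gets a
  log-transform recommendation, never an automatic transform) and global
  Moran's I with row-standardized inverse-distance weights and a one-sided
  permutation p-value (999 permutations by default, seeded). Kriging a
  field with no spatial autocorrelation is numerology; the pipeline warns
  rather than aborts unless asked, since small surveys can fail screening
  for benign reasons.
* **Variography.** Method-of-moments semivariogram on 12 lag bins up to
  half the maximum pairwise distance (both overridable); bins carry their
  pair counts and mean pair distance. Model families: spherical,
  exponential, Gaussian (all parameterized by their *practical* range —
  the exponential and Gaussian reach 95% of the sill there) plus a pure
  nugget. Fitting is pair-count-weighted least squares with bounded
  multi-start over the range axis (the WLS objective is multimodal).
* **Selection.** Leave-one-out cross-validated kriging RMSE ranks the
  fitted families; ties break toward fewer parameters, then the canonical
  family order. With one candidate the ranking is a pass-through.
* **Kriging.** Per-cell ordinary kriging from the 32 nearest samples
  (overridable), solved with a Lagrange multiplier so weights sum to one;
  kriging variance is reported per cell. γ(0) = 0 exactly, so a nugget-free
  model interpolates the samples exactly. Duplicate sample coordinates are
  averaged at ingest (they make the system singular); any still-singular
  cell is masked with a warning rather than silently filled. Neighbor
  Gram matrices are gathered from a single precomputed sample-pair
  semivariance matrix and solved in batched chunks.

## Spillover model

Given kriged before/after surfaces Lp^β, Lp^α on a shared grid (15 m cells
by default — the resolution of graded urban-land analysis):

1. r = (mean Lp^α − mean Lp^β)/mean Lp^β over the study region removes the
   market-wide price rise and shared location effects;
2. the excess surface Lp^α − Lp^β(1 + r) isolates growth beyond that trend;
   its positive part defines the impact range (negative cells are kept in
   the grid for inspection but excluded from valuation, so SEV ≥ 0);
3. SEV = Σ_plots Σ_{cells in plot ∩ mask} excess × cell area, with
   cell-center-in-polygon membership (raster-calculator semantics, so
   results are bit-reproducible).

The averaging in step 1 uses surface cells, not sample points, because the
differencing in steps 2–3 is raster algebra; a region mask can narrow it.
The rise is carried per land-use type in the data model, though a survey
with only residential samples uses a single r. No detrending is applied
before kriging and no log back-transform correction is made: the model
operates on raw price surfaces.

Two intrinsic biases of this estimator are worth naming. The regional mean
in step 1 *contains* the spillover itself, so r is slightly inflated and
SEV slightly deflated in proportion to the kernel's share of the region —
small when the study region is much larger than the influence zone.
Conversely, clipping to the positive mask converts symmetric interpolation
noise into a positive SEV contribution wherever the true excess is near
zero; plots far from the restored site therefore accumulate spurious
value. The null-scenario test below quantifies exactly this.

## Synthetic ground truth

**Land cover.** Class-area targets (any 2-decimal hm² value at 10 m cells)
are converted to exact cell counts and laid out by seeded multi-source
region growth: classes claim random frontier cells in interleaved batches,
re-seeding when enclosed, so the map is spatially clustered like an
interpreted satellite product rather than i.i.d. noise. Areas are exact by
construction for any seed. The bundled study-area fixture reproduces the
published before/after landscape structure (total 5,309.42 hm²) this way.

**Prices.** The two-epoch scenario is

    Lp^β = baseline(x) + Z(x),
    Lp^α = (1 + g)·Lp^β + δ(x) + K(x),

with baseline 350 yuan/m² plus a ±5% west–east gradient; Z a zero-mean
Gaussian random field with a spherical variogram (nugget 50, sill 600,
range 1,200 m) synthesized by circulant embedding (negative embedding
eigenvalues clipped — a standard approximation, negligible at the padding
used); g = 1.7681 the regional growth of a fast-urbanizing decade; δ an
independent innovation field holding 5% of the after-epoch residual
variance (price structure mostly persists between epochs — the premise of
excess-price differencing — but not perfectly); and K a conical uplift
kernel A·max(0, 1 − d/R), A = 350 yuan/m², R = 900 m, centred on the
restored wetland. Samples (47 and 61 per epoch by default, the scale of a
county land-price survey) carry nugget-consistent observation noise; 40%
fall within 1,200 m of the site, because surveys concentrate where
residential land actually exists — the urbanizing fringe around the park.
The default planned-plot set is the corresponding residential ring: twelve
300 m plots at 450 m radius (108 hm²). SEV_true is the kernel's zonal
integral over the plots, evaluated at 2.5 m; a disk-covering plot checks it
against the closed-form cone volume πAR²/3.

The scenario's noise levels were set by an explicit error budget so that
the estimator is *diagnostic* at the validation sample size (300/epoch):
kriging error must be small against the kernel, or recovery failures would
measure the scenario, not the method. Rougher fields or sparser sampling
degrade recovery for the intrinsic reasons given above — that behavior is
real, not a defect, and the far-plot clipping effect is exercised
explicitly in tests rather than buried in the default conditions.

**What passing does not show.** The synthetic fields are stationary,
isotropic and Gaussian with a single known kernel; real land prices have
trends, anisotropy along roads, submarket discontinuities and surveys
clustered by administrative convenience. Recovery within tolerance here
validates the implementation and the estimator's behavior under its own
assumptions, not the transferability of any particular published SEV.

## Numerical choices and degenerate inputs

* Table-facing numbers round half-up at the table's precision; internal
  arithmetic is full double precision.
* Variogram fit bounds: nugget ≥ 0, partial sill ≥ 0, range ∈ (0, 2·max
  lag]; eight multi-start ranges geometrically spaced.
* Kriging weight sums are asserted to 1e−8; kriging variances are clipped
  at zero (tiny negatives from finite arithmetic).
* Constant prices: normality and Moran's I raise (statistics undefined).
  All-coincident points: variography raises. All-nodata grids: tabulation
  raises. Mismatched grid geometries or area totals: hard errors, since
  silent resampling would corrupt the accounting.
* Non-positive synthesized prices are resampled with a warning (prices are
  strictly positive by definition); twenty failures abort.
* Every stochastic routine takes an explicit seed; identical seed and
  configuration reproduce byte-identical outputs.

## Problem sizes

The validation suite runs the full published-structure fixture (531,441
cells per epoch) for the valuation chain, and the spillover recovery and
null experiments at 20 seeds × 300 samples/epoch on the 6 km × 6 km, 15 m
scenario grid (160,000 kriged cells per epoch per seed). Unit tests use a
reduced 3 km / 30 m scenario.

## Known limitations

* Variogram *range* identification from a single realization is fragile
  whenever a deterministic trend is present (the no-detrending workflow
  cannot separate a weak price gradient from long-range correlation — the
  empirical variogram keeps climbing and the fitted range inflates), when
  sampling concentrates in one correlation patch, or when the range is not
  small against the domain. On a trend-free, uniformly sampled stationary
  field the fitted range is reliable; under the realistic survey scenario
  it is not, and the validation suite measures exactly that. Predictions
  are far less sensitive than the range parameter itself (cross-validated
  RMSE, not parameter truth, drives model selection), which is why SEV
  recovery succeeds while range recovery degrades.
* Isotropic variograms only; no universal/co-kriging, no Bayesian
  uncertainty on the variogram parameters (selection uncertainty is
  reported via the LOO table, not propagated).
* A single global r per land-use type; no spatially varying trend removal.
* Plot membership by cell center can misassign boundary slivers narrower
  than a cell; at 15 m cells against hectare-scale plots this is the
  documented raster semantics, not an accuracy claim.
* The published after-reclamation table carries two cells inconsistent
  with its own landscape areas (transportation, built-up); validation uses
  the arithmetically consistent cells and the published totals, and the
  fixture records both.
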