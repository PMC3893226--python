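# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Acoustic target processing

**TS–length relation.** Target strength of a swim-bladdered fish scales with
log body length. We adopt the generalized Love-form relation

    TS = 19.1·log10(L_cm) − 0.9·log10(f_kHz) − 62.0   (dB re 1 m²)

and its inverse for length estimation. At 120 kHz the −50 dB retention
threshold corresponds to a 5.32 cm fish, consistent with the usual reading of
that cutoff as "about a 6 cm fish". All three constants are arguments of
`ts_to_length`/`length_to_ts`, since published variants of the relation
differ slightly.

**Thresholding and size classes.** Targets with TS ≥ −50 dB are retained
(the boundary is kept; the convention is configurable). Lengths are rounded
to the nearest centimetre before classing so the integer class bounds
partition cleanly: small ≤ 11 cm, medium 12–28 cm, large ≥ 29 cm. These
classes separate small reef residents/planktivores, larger reef residents and
juveniles of fished species, and adult fishery species respectively.

**Equal-ensonified-area binning.** A splitbeam beam of full angle 7° has
seafloor footprint width w(d) = 2·d·tan(3.5°) ≈ 0.12·d, so a fixed
along-track bin would sample more area over deep water. `bin_survey`
integrates w(d)·ds along the track and closes a bin whenever the accumulated
ensonified area reaches 100 m²; every bin then has exactly 100 m² of area
and an along-track length that shrinks with depth (16.35 m at 50 m depth).
Targets are snapped to the nearest track station and assigned by along-track
interval, ties toward the earlier bin; targets outside the local half-width
w/2 were never ensonified and are not counted. Empty bins are kept — zeros
are the absences occurrence models are trained on. A fixed-length binning
mode is available for comparison.

## Terrain predictors

Six base surfaces are derived from the depth grid, then each is averaged
over circular windows of radius 25, 50, 100 and 300 m (cells whose centres
fall within the radius), giving 6 × 4 = 24 predictor layers named
`surface@radius`. Only the focal means enter the default stack; native-
resolution layers can be added with `include_native=True`.

| surface | definition | units |
|---|---|---|
| depth | water depth, positive down | m |
| depth_sd | population SD of the 3×3 neighborhood | m |
| plan_curv | Zevenbergen–Thorne plan curvature on the elevation surface, convex positive, ×100 | — |
| dist_shelf | Euclidean distance to the 183 m isobath | km |
| rugosity | Jenness 8-triangle surface area / planar area | ≥ 1 |
| slope_of_slope | Horn slope of the Horn slope raster | °/° |

Numerical conventions, chosen so each kernel has an exactly matching
brute-force oracle in the tests:

- `focal_sd` and `focal_mean` shrink their window at grid borders (statistics
  over available cells only) rather than emitting nodata, so the shallow
  shelf margin survives; derivative kernels (slope, curvature, rugosity) use
  nearest-edge padding, the common DEM convention.
- The isobath is defined on the cell lattice: cells at or below 183 m depth
  with a 4-neighbour above it. Distances are exact Euclidean
  (`distance_transform_edt`), computed in metres and reported in km. A grid
  without a crossing raises an error asking for a larger domain.
- Curvature cells with zero gradient return 0 by convention. The ×100
  output scaling matches conventional raster curvature products and is a
  module constant.
- Focal means use FFT convolution with a nodata-aware normalisation
  (sum of valid values / count of valid cells), agreeing with the
  double-loop oracle to better than 1e-9 relative.

## Boosted regression trees

`fit_brt` is classic stochastic gradient boosting: each stage fits a CART
regression tree (scikit-learn `DecisionTreeRegressor`, grown best-first to
`tree_complexity` + 1 terminal nodes) to the pointwise deviance gradient on
a fresh `bag_fraction` subsample, replaces its leaf values by one Newton step
for the family, and shrinks by `learning_rate`. Families: `bernoulli` for
occurrence (presence = density > 0), `poisson` for per-bin counts (bins have
equal 100 m² area, so expected counts are densities), `gaussian` as a
fallback. Leaf Newton steps are clipped to ±4 for numerical safety.

**Tree-count selection.** K-fold cross-validation boosters grow in lockstep
blocks of `step_size` trees; after each block the mean holdout deviance is
recorded, and growth stops once no new minimum has appeared for `patience`
consecutive blocks (or at `max_trees`). The final model is refit on all rows
at the argmin tree count. A model whose CV deviance never beats the intercept
is flagged *degenerate* — the package's analogue of "performs no better than
random" — keeps zero trees, predicts the base rate, and reports zero
influence. Degenerate replicates are expected and common for responses with
little terrain signal.

**Settings.** `BRTConfig` defaults follow common working-guide practice for
large ecological datasets (learning rate 0.005, tree complexity 5, bag
fraction 0.5, 10 folds, up to 10 000 trees). The pipeline's default
(`desk_brt_config`: learning rate 0.05, tree complexity 3, 5 folds, step 25,
max 250 trees, patience 2) is sized for the few-hundred-bin synthetic
surveys this package runs end-to-end; with ~1300 bins and 24 predictors the
selected models use tens to a few hundred trees.

**Interpretation.** Relative influence is each predictor's share of the
total squared-error improvement of its splits across all selected trees,
normalised to 100. Partial dependence evaluates the model over one
predictor's training range with every other column fixed at its training
mean. Ensembles (`fit_ensemble`) are replicate models on independent random
50 % train/holdout splits with seeds derived from a master seed; predictions
average arithmetically on the response scale, cell-wise for rasters.

**Change of support.** Models are trained on 100 m² bins but predict onto
2 m cells; density predictions are therefore expected counts per 100 m² of
ensonified area, not per-cell counts.

## Transfer validation

Validation in the second area follows the sequence: random subsample
(fraction 0.5) → local-polynomial detrend → empirical semivariogram →
spherical fit → thin to the fitted range → metrics on the survivors.

- **Detrending**: LOESS-style local quadratic in (easting, northing),
  tricube weights, nearest-neighbour span 0.5; collinear geometry falls back
  to a global quadratic with a warning.
- **Semivariogram**: 15 equal-width lag bins; the generic default support is
  half the maximum pairwise distance, while the pipeline uses one third —
  beyond that, bins mostly carry sill information and edge effects.
  The spherical fit is multi-start bounded least squares over (nugget,
  partial sill, range) with weights N(h)/h²: plain pair-count weights let
  the far bins (most pairs) swamp the short lags that identify the range,
  which measurably degrades range recovery. The range is only identifiable
  inside the lag support; fits at the 3×-support bound or with a vanishing
  partial sill are flagged.
- **Thinning**: seeded random-order greedy selection; the retained set
  provably has min pairwise spacing ≥ the range and is maximal. When the
  variogram is flagged pure-nugget there is no autocorrelation and nothing
  is thinned; when it is flagged at the support bound the thinning distance
  is capped at half the maximum empirical lag — a desk-scale study window
  cannot justify thinning distances beyond what its own extent resolves.
- **Scores**: binary AUC by the tie-corrected rank formulation
  (Mann–Whitney), 95 % CI half-width by the Hanley–McNeil variance formula
  (a stratified bootstrap would be the heavier alternative). Densities are
  classed by exact Fisher–Jenks natural breaks (dynamic program, verified
  against exhaustive enumeration) into absent-to-low/low/medium/high; the
  continuous predicted density scores every class pair's ROC, and the
  Hand–Till multiclass AUC M is the mean of the pairwise AUCs, excluding
  (with a warning) pairs where a class has fewer than 2 members. MAE/RMSE
  are complemented by residual classes relative to the MAE (±, ≤/> MAE).
- **Error clustering**: Anselin Local Moran's I with row-standardised
  inverse-distance weights (power 1), 199 conditional permutations in the
  pipeline (999 as the function default), two-sided pseudo-p, α = 0.05;
  significant points are labelled HH/LL clusters or HL/LH outliers. With
  row-standardised weights the mean of the local statistics equals global
  Moran's I, which the tests verify against an independent implementation.

## Synthetic seascape generator

The generator is first-class, tested code; its defaults define the study
conditions for the whole test battery.

**Bathymetry.** Depth = cross-shelf ramp + broad Gaussian random field
(amplitude 1.5 m, correlation 50 m) + fine reef-texture field (amplitude
1.1 m, correlation 6 m) modulated by a smooth patchiness envelope
(correlation 60 m, half-rectified so roughness occurs in discrete patches).
The ramp runs 28 → 100 m across the study window (cells 0…255 of a 384 × 320
grid at 2 m), then drops steeply to 230 m in a border strip, so the 183 m
shelf-edge isobath always exists in-domain but outside the analysis window —
matching the geometry of shelf surveys whose depths stay ≤ 100 m yet whose
distance-to-shelf-edge predictor needs the 183 m contour. Depths are floored
at 22 m, the shallow end of the emulated survey envelope. The window is
roughly 0.5 × 0.77 km — two orders of magnitude smaller than a real survey
area, chosen so a full two-area run takes ~1 minute; correlation lengths
(50–60 m) are correspondingly shorter than real reef-scape ranges
(~300–500 m) so the spatial structure is resolvable inside the window.

**Survey.** Serpentine north–south lines (parallel to the depth contours of
the ramp), default spacing 24 m, a vertex every 10 m; ~1300 bins of 100 m²
per area.

**Fish.** Per size class an inhomogeneous Poisson field with log-linear
intensity

    log λ(fish / 100 m²) = β0 + β_depth·1[depth < 38 m] + β_sd·1[depth_sd > 0.29 m]

(step terms by default; linear forms available), capped at a carrying
capacity of 20 fish/100 m² so realised densities stay within the observed
0–33 range. Lengths are log-normal truncated to the class interval;
positions are uniform within cells; TS is the forward Love-form value plus
optional Gaussian noise. The built-in **training** and **validation**
scenarios share the large-fish model (β_depth = 2.0, β_sd = 1.5 on the
native 3×3 depth-SD) but give small and medium fish a higher baseline in the
validation area (e.g. small: e^β0 = 1.1 vs 2.2 fish/100 m²), reproducing the
prevalence-mismatch failure of transferred models for smaller fish.

The **recovery scenario** (`large_fish_recovery_scenario`) exists for
parameter-recovery checks: β0 = log 0.02 and β_depth = β_sd = 5 make
occurrence nearly deterministic in habitat, and its depth-SD term reads the
25 m focal mean — a member of the model's own predictor set — so influence
attribution is well-posed. With the native SD, the roughness signal is
informationally shared among depth-SD, rugosity and slope-of-slope (all
monotone proxies of the same latent roughness) and the boosting stage may
attribute it to any of them; that collinearity is a real feature of terrain
predictors, not an implementation artefact. The β magnitudes were sized from
the generating model's own discrimination ceiling before any boosted model
was fit to the scenario.

**What passing tests do and do not show.** The generator produces the
features the pipeline consumes — realistic density magnitudes, prevalence
patterns, terrain-linked structure, TS–length consistency — but real SBES
data add target-detection error, tracking mis-association, vessel avoidance,
diel movement, species mixtures within size classes, and MBES depth
uncertainty, none of which are emulated. Passing tests demonstrate the
analysis chain is correct and recoverable under known ground truth, not that
any ecological conclusion transfers to a particular reef.

## Numerical and I/O choices

- Rasters are exchanged as ESRI ASCII grids (text, nodata −9999); points and
  bins as CSV with documented schemas (`%.17g` floats for lossless round
  trips); models as a JSON schema with self-contained split arrays, so saved
  models predict without unpickling.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; per-area, per-response and per-replicate
  seeds are derived, so any component is independently reproducible and the
  whole pipeline report is identical across runs of the same config.
- Degenerate inputs are handled explicitly: constant responses (intercept
  model), constant fields (zero Moran's I, zero residuals), single-class
  labels (error), pure-nugget variograms (flagged, no thinning), grids
  without an isobath (error with remediation hint).

## Known limitations

- The serpentine track follows the ramp's mean contour direction rather than
  actual curved isobaths; contour-following on arbitrary bathymetry is not
  implemented.
- Poisson density models assume independent counts given terrain;
  overdispersion (schooling) is not modelled, consistent with the
  generator's Poisson draws but optimistic for real aggregations.
- Variogram ranges estimated from a single realisation carry irreducible
  field-to-field variability (~10–15 % SD at 500 points); downstream
  thinning inherits it.
- No interaction-strength estimation or predictor-dropping routine for the
  boosted models; no spatial cross-validation folds; no kriging from the
  fitted variogram (it only sets the thinning distance).
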