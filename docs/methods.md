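# Methods

## Scope and data model

All spatial inputs are single-band ESRI ASCII grids sharing one header
(`ncols, nrows, xllcorner, yllcorner, cellsize, nodata_value`); row 0 is the
northern edge. No projections or resampling are handled — layers must be
co-registered upstream. Cells are half-open: a point maps to
`c = floor((x − xll)/cs)`, `r = nrows − 1 − floor((y − yll)/cs)`, and points
on the east/north boundary of the grid are rejected so no point can belong
to two cells. Nodata is matched by exact equality after parsing (default
−9999, the format's convention); a stack's validity mask is the
intersection of its layers' valid cells. Writing uses `repr`-precision
decimal text, so a write/read round trip is bit-exact.

## Presence and background

Occurrence records are deduplicated onto grid cells (the modelling unit);
records off-grid or on nodata are dropped with logged counts rather than
erroring, since field coordinates are routinely messy. Background
eligibility is the literal cultivation rule: precipitation **strictly**
below 250 mm or **strictly** above 400 mm, or elevation **strictly** below
800 m — boundary values are not eligible. Each ensemble iteration draws a
fresh, seeded, uniform without-replacement sample of background *cells*
(presence cells excluded) of the same size as the presence set, giving a
balanced 2n-row training table.

## Boosted regression trees

The BRT is standard stagewise gradient boosting on the Bernoulli deviance,
written here from first principles:

* `F₀ = log(p̄/(1−p̄))`; per iteration a `bag_fraction` subsample is drawn
  without replacement, a regression tree with at most `tree_complexity`
  splits is fitted to the pseudo-residuals `y − p` by best-first leaf
  expansion (each split maximises squared-error reduction), terminal values
  are one-step Newton estimates `Σ(y−p)/Σp(1−p)` clamped to |10| (the clamp
  guards separable leaves), and `learning_rate` times the tree is added to
  the score.
* Categorical splits search all subsets exhaustively up to 10 observed
  codes; beyond that, codes are ordered by in-node mean residual and split
  as if ordered. At prediction, codes unseen at a node follow the child
  with more training weight, with a logged count — raster cells routinely
  hold codes absent from a particular training bag.
* Determinism: all randomness flows from `FitConfig.seed` through
  `numpy.random.SeedSequence` spawning; split ties break toward the lower
  predictor index and lower threshold; refits are bit-identical.
* Leaves require `min_obs_in_node` (default 10) in-bag rows, matching the
  common default of reference GBM implementations.

The ensemble size is chosen by stratified 10-fold cross-validation grown in
increments of `step_size` (10): fold models are extended in lockstep while
pooled held-out deviance is tracked, stopping after `patience` (5)
checkpoints without improvement or at `max_trees`; the optimum is the
checkpoint with minimal held-out deviance (hence always a multiple of
`step_size`), and the reported AUC is the mean per-fold held-out AUC at
that optimum — never a training-set number. AUC itself is the Mann–Whitney
pair statistic computed via midranks (ties count ½).

Relative contribution sums each predictor's split improvements over the
used trees and normalises to 100%. Partial dependence forces one predictor
to a quantile grid (observed codes for categoricals) and averages predicted
probability over the data rows; tests verify it against exhaustive
row-by-row forcing.

## Ensemble aggregation

Each of `n_iterations` (default 200; 10 at demo scale) iterations redraws
background, reselects the tree count by CV, refits on the full training
table and predicts the whole raster. Aggregates: cell-wise mean and
**population** (divide-by-N) standard deviation — a descriptive uncertainty
surface; unweighted mean of per-iteration RC vectors renormalised to 100%;
the list of per-iteration cross-validated AUCs. Iterations that fail are
skipped and logged; more than 10% failures aborts. Main factors are those
with mean RC above `rc_threshold` (default 2%), flagged when their
cumulative RC exceeds 95%.

## Quality regressions

Stepwise OLS uses forward entry by smallest partial-F p-value (< 0.05) and
backward removal by largest drop-one p-value (> 0.10), the long-standing
defaults of desktop statistics packages; thresholds are configurable, and
`p_enter ≤ p_remove` is enforced to prevent cycling. Coefficients come from
`numpy.linalg.lstsq`; collinear candidates (rank-deficient trials) are
skipped with a log entry. R² is `1 − RSS/TSS` of the final model.

In the pipeline the candidate set is the *continuous* main ecological
factors that appear as sample-table columns: integer category codes have no
meaningful linear effect, so categorical factors (e.g. soil type) are
deliberately excluded from the linear quality models even when their RC is
large. The five published equations are available verbatim as
`builtin_equations()` (units assumed: BIO1 °C, BIO3 dimensionless sd×100,
BIO4 mm, contents % dry mass; the compound named "loganic acid and
gentiopicroside" is treated as the sum of the two contents). Applying an
equation is cell-wise linear algebra with nodata propagation; negative
predicted contents are kept (the overlay normalises) but counted in the run
report as an extrapolation flag.

## Overlay and classification

How the published analysis combined the compound layers with suitability is
not specified; this package min–max-normalises each layer over valid cells
and multiplies them (configurable to `min`), on the reasoning that a
high-quality growing area must score high on *both* axes. With several
compound layers the quality layer is the mean of the normalised per-compound
rasters. Natural breaks use the exact Fisher–Jenks dynamic programme over
the sorted distinct values weighted by multiplicity; split positions are
restricted to boundaries between distinct values because classification is
by value and tied values must share a class. DP ties resolve toward the
smaller lower class. The DP is O(k·n²), so rasters larger than `subsample`
(default 10,000) valid cells contribute a seeded random subsample to the
break computation; the breaks are then applied to every cell. Breaks are
class maxima: class = 1 + number of breaks strictly below the value.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
real geography. Continuous layers are a linear gradient plus a Gaussian
field smoothed by a fixed-width moving average (default 3 cells — enough
spatial autocorrelation to resemble climate layers); categorical layers are
nearest-seed Voronoi patches. The truth function is
`logistic(scale · (s_elev + s_precip + s_cat))` with centred component
scores: `s_elev` rises smoothly through zero at the elevation threshold
(default 1,500 m, matching the species' montane optimum), `s_precip` is a
plateau maximal inside the 250–400 mm band decaying smoothly outside, and
`s_cat` adds per-code offsets. Centring makes "all effects zero" yield a
uniform 0.5 surface, which the tests rely on. Occurrences are drawn
cell-wise proportional to suitability with within-cell jitter and possible
duplicates (so deduplication is exercised). Compound contents are the
published equations (remapped onto scene layer names) plus additive
Gaussian noise calibrated so the population R² matches a target (default
0.35, the magnitude of the published fits); negative contents are clipped
at zero with a logged count. One master seed drives everything via
`SeedSequence` spawning.

What passing tests on this generator do **not** show: behaviour under real
spatial sampling bias, variogram-realistic autocorrelation, non-linear
climate–compound relationships, or covariate collinearity patterns of real
WorldClim-style layers.

## Problem sizes

The demo/acceptance configuration — 32×32 grid, 6 layers, 60 occurrence
draws (~55 presence cells), 10 ensemble iterations, `max_trees` 300, all
other boosting parameters at the full-design values — was chosen as the
smallest scene on which the strong-signal truth function cleanly exceeds
the AUC ≥ 0.75 robustness criterion; it completes in about a minute on one
CPU. The full design (200 iterations, `max_trees` 10,000) is the package
default and scales linearly in iterations.

## Known limitations

* Permutation importance is not implemented; predictor importance is RC
  only.
* No GeoTIFF/CRS support; `.asc` with pre-aligned headers is the only
  spatial format.
* Stepwise selection inherits the usual caveats (post-selection inference
  is optimistic; p-values are conditional on the selected model).
* The per-iteration AUC is the cross-validated AUC of that iteration's
  training table, not an independent spatial hold-out; with few presence
  cells it is optimistic in the usual CV sense.
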