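# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design being modelled

A herd of GPS-collared female caribou is monitored through five summer
periods — calving (Jun 1–15), post-calving (Jun 16–30), mosquito
harassment (Jul 1–15), oestrid-fly harassment (Jul 16–Aug 7), late summer
(Aug 8–Sep 15) — with fixes every 2 h (3 h in early collar years).
Selection is estimated at two scales: the placement of seasonal use within
the herd's range (landscape scale), and the choice of the next step's
endpoint (patch scale). Calving is split by parturient status; the insect
seasons are split into predicted high/low harassment periods.

## Preprocessing

* **Screening.** 2D fixes and fixes with PDOP strictly greater than 10 are
  removed, as are duplicate timestamps (first kept), non-finite
  coordinates, and fixes implying > 50 km/h from the previous retained fix
  ("erroneous points" are not quantified in the source design; the speed
  and duplicate rules are this package's operationalization, reported
  separately in the `ScreenReport`).
* **Sedentary filter.** A fix is retained iff it moved more than 25 m from
  the previously *retained* fix. This automatically retains the first
  location of a sedentary bout (the last fix that moved) and drops the
  rest of the bout; the first fix of every animal(-season) is always
  retained. The filter is idempotent.
* **Seasons** are assigned on local dates (fixed UTC−8 offset,
  configurable), with month–day windows inclusive on both ends.
* **Herd switches.** An animal-year is excluded (with all later years of
  that animal) if a calving-season fix in a season after the animal's
  first falls inside another herd's calving polygon.

## Insect activity index

The historical index's functional form is not public; the package uses the
minimal separable form consistent with its published corner conditions:

    index = clamp01((T − T_lo)/(T_hi − T_lo)) × clamp01((W_hi − W)/(W_hi − W_lo))

with T_hi = 18 °C and W_lo = 0 for both taxa, (T_lo, W_hi) = (6 °C, 6 m/s)
for mosquitoes and (13 °C, 9 m/s) for oestrid flies. The index is 1 at the
hot-calm corner, 0 whenever T ≤ T_lo or W ≥ W_hi, and monotone everywhere.
A fix is classified *high* when the index exceeds 0.5 (strict) at any
record of either station in the half-open window (t−12 h, t]; an empty
window yields *unknown* and the fix is excluded downstream with a logged
count. A sensitivity variant lowers the mosquito wind cut-off to 4 m/s.
The parameters live in `InsectIndexParams` so an alternative form can be
swapped without touching callers.

## Covariates

* **TTLQV.** The three-term local quadrat variance of a class indicator,
  V3(b) = mean over positions of (S1 − 2·S2 + S3)²/(8b) for block sizes
  b = 1..max_block, computed along all rows and all columns and averaged
  (the transect statistic has no canonical 2-D form; row/column averaging
  is this package's choice). The density window is the b* maximizing V3.
  *Known property:* for a balanced square-wave mosaic of patch width w the
  V3 peak sits at ≈ 0.93 w in the continuous limit (first-harmonic
  analysis: maximizing sin⁶(πb/2w)/b gives b/w ≈ 0.926), so the detected
  integer scale is w or w−1 depending on rounding — a ~7% downward bias
  of the statistic itself, not of the implementation, which is verified
  against a nested-loop oracle to machine precision.
* **Moving-window density**: proportion of class-k cells among valid
  (non-water) cells in a centred square window (side forced odd), with
  truncated windows at edges. Computed with separable uniform filters.
* **VRM**: unit surface normals from Horn 3×3 finite differences (border
  gradients replicated from the interior so planar surfaces stay exactly
  planar to the edge), resultant-vector length R over a w×w window,
  VRM = 1 − R/n. Exactly zero for flat and uniformly inclined planes;
  invariant to elevation offsets. The 8-pixel window is interpreted as
  8×8 (the alternative 3×3-of-8-neighbours reading is noted but not used).
* **NDVI phenology** from 10-day composites: green-up = first composite
  above 0.1; max growth = date of the maximum (earlier date on ties);
  senescence = first date after max growth below 0.1; pixels never
  exceeding 0.1 are no-data. Where all three are defined,
  green-up ≤ max-growth ≤ senescence.
* **Distance to coast**: exact Euclidean distance transform × cell size.
* **Design matrices**: vegetation one-hot with sedge–grass meadow omitted
  (reference class); log(x + cell_size) on elevation and distance to coast
  (the additive guard handles exact zeros; the source design is silent on
  them); √ on VRM; z-standardization over the combined used+available
  sample of the season being fitted, with the means/SDs stored and reused
  verbatim for map prediction; squared terms added after standardization.
  Whether the original standardization pooled used+available or
  availability only is unknown; pooling is the default here.
* **VIF pruning** drops the single highest-VIF column (∞ for perfect
  collinearity, and constant columns first) and recomputes until all
  VIF < 3; terminates in at most #columns − 1 iterations.

## Sampling designs

* **Range isopleth**: points binned on a grid and smoothed with a Gaussian
  kernel (per-axis normal-reference bandwidth h = σ̂·n^(−1/6), the "ad hoc"
  rule of the home-range literature; configurable); the isopleth is the
  smallest density threshold whose super-level set carries ≥ 95% of the
  mass. Grid-cell membership stands in for the polygon; a shapely polygon
  is derivable for export.
* **Landscape availability**: rejection sampling, uniform over
  range ∩ land, 1:1 with used points, seeded. Water screening defaults on
  (a flag disables it).
* **Step availability**: per animal-season empirical sets of movement
  *rates* (m/h, so mixed 2/3-h intervals are respected) and *absolute
  bearings*; five independent with-replacement draws per used fix,
  displaced from the previous fix; candidates off-raster or on water are
  redrawn (≤100 rounds), and strata that cannot be filled are dropped with
  a log entry. Strata are exactly 1 used + 5 available.

## Models

* **Landscape GLMM.** Bernoulli logit with crossed random intercepts
  (animal, year), estimated by a Laplace approximation: spherical
  parametrization η = β₀ + Xβ + Σ_f sd_f Z_f v_f with penalty ‖v‖²/2;
  penalized Newton inner loop; outer Nelder–Mead over the SDs with β
  profiled, followed (at low fixed-effect dimension) by a joint
  Nelder–Mead refinement over (β, SDs) with v profiled — the same
  objective glmer maximizes at nAGQ = 1, and the two agree to ~1e-3 on
  test fixtures. The boundary sd = 0 is well defined and reduces exactly
  to pooled logistic regression (`re_sd_fixed` pins SDs for this and for
  sensitivity analyses). Fixed-effect covariance is the corresponding
  block of the inverse penalized information.
* **Conditional logistic.** Exact stratified likelihood, analytic gradient
  and Hessian via grouped reductions, Newton with backtracking to gradient
  norm < 1e-8; separation raises a named error (covariate constant within
  every stratum, or diverging estimates); strata where a covariate is
  constant trigger a warning (they carry no information for it).
* **Model selection.** All-subsets AIC over covariate blocks (vegetation
  dummies as one block), ties toward fewer parameters. Non-linearity
  screening compares single-variable logistic fits with and without a
  square term and keeps the square when ΔAIC > 2 (the detection rule is
  unspecified in the source design; ΔAIC > 2 is this package's logged,
  configurable choice). At the landscape scale the default is to fit the
  full post-VIF covariate set, with all-subsets available as an option.
* **Robust SEs.** Per-stratum summed deviance residuals, centred by an
  intercept-only random-intercept model grouped by animal, ordered in
  time; the correlation lag is the smallest L with |ACF(L)| < 1.96/√m per
  animal (maximum over animals, minimum 1; animals with < 10 strata fall
  back to 1 with a warning). Strata are assigned to two groups in
  alternating blocks of length `lag` within each animal's time order, the
  model is refitted on each, and the robust covariance is the average of
  the two group covariances. Whether the lag should count strata or hours
  is unspecified; strata counts are used here.

## Validation and mapping

k-fold validation partitions *animals* (not points) into k = 5 folds, so
serial correlation cannot leak across the split; withheld used points are
tallied across 10 equal-area bins defined by withheld available-point
score quantiles; ρ̄ is the mean over folds of the Spearman correlation
between bin rank and area-adjusted used frequency, and the p-value is a
one-sided Spearman test on the fold-averaged frequencies (the published
table's p construction is not stated; this choice is logged). Prediction
surfaces apply the stored training transforms pixel-wise and the logistic
form w(x); patch-scale fits have no intercept, so their surfaces use β₀=0
and are meaningful only relatively (the decile-classed variant is
intercept-free by construction). Water cells are no-data everywhere.

## Synthetic data: what it emulates, and what it does not

* **Vegetation**: a Gaussian random field with a band-pass
  (difference-of-Gaussians) covariance — tundra mosaics (patterned ground,
  ice-wedge polygons) have a characteristic alternation scale, which a
  low-pass field lacks — thresholded at class-proportion quantiles over
  land, which reproduces the target composition (defaults: the nine-class
  scheme at 7/2/5/5/6/27/1/43/4 percent) exactly up to cell rounding
  while keeping classes clumped. Lakes (~5% cover) come from a coarser
  field; the coast is the northern grid edge.
* **Terrain**: smooth field plus a gentle inland rise scaled to 60 m
  relief (a low-relief coastal plain). **NDVI**: Gaussian seasonal curves
  (10-day composites) whose peak day and amplitude vary smoothly in space
  and cross the 0.1 threshold. **Weather**: hourly diurnal cycles
  (temperature peaking ~16:00) plus AR(1) synoptic anomalies with
  negatively correlated temperature and wind (warm spells calm, windy
  events cool), which makes all four insect-index corner regions occur in
  any summer month.
* **Movement**: gamma step lengths (shape 2, mean 300 m per 2-h step) and
  von Mises turns (κ = 0.5); each step the animal draws K = 30 candidate
  endpoints, rejects water (reflecting proposals at the raster edge), and
  picks one with probability ∝ exp(βᵀx). Covariates named in β are class
  indicators or per-SD standardized continuous layers. A configured 2.6%
  of fixes receive 2D/high-PDOP noise flags (1.5% + 1.1%, disjoint).
  The vegetation grain (120 m autocorrelation) is finer than a step, so
  candidate endpoints sample nearly independent habitat.
* **Not emulated**: real geography, behavioural states beyond the
  selection coefficients, collar duty cycling, spatially varying insect
  abundance, NDVI cloud artefacts. Passing recovery tests therefore show
  the estimators are correct *under the stated generating assumptions*;
  they do not certify performance under misspecification on real data.

## Known quantitative limitations

* **SSF attenuation.** The candidate-choice generator with finite K is
  itself a choice model: the used point's marginal density is
  g(x)·exp(βᵀx)·ψ(x) with ψ decreasing in x, an O(1/K) attenuation; the
  empirical rate/bearing resampling used for estimation (absolute bearings
  vs persistent headings; realized vs proposal steps) adds a little more.
  The recovery experiment (20 datasets of 20 animals × 500 steps,
  β = (1.0, −0.5, 0.3)) measures mean absolute bias below 0.1 on every
  coefficient, but with ~10,000 strata the robust SEs are small enough
  that this attenuation keeps 95% CI coverage near — not comfortably
  above — 85%.
* **TTLQV peak bias** of ≈ −7% on balanced mosaics (see above).
* The Laplace approximation shares glmer's small-cluster bias for binary
  responses; the recovery experiment (50 clusters × 40 observations,
  SD = 1) recovers the SD and fixed effects well within ±0.3.

## Problem sizes

Default experiment sizes — a 160–250 cell square grid at 30 m, 8–20
animals, 300–1,284 steps per animal, 20-repetition recovery experiments —
were chosen so the full demo and every experiment each run in seconds to
a couple of minutes on a single core while leaving Monte-Carlo error well
inside the asserted tolerances.
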