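# caribou-rsf

Two-scale summer **resource selection function (RSF)** analysis for
barren-ground caribou, built as a reusable, tested pipeline: from raw GPS
collar fixes and environmental rasters to fitted selection models,
autocorrelation-robust standard errors, cross-validation, and
relative-probability-of-use maps.

The package is aimed at movement ecologists and wildlife analysts who work
with used–available designs on arctic telemetry data. Because real collar
data and agency vegetation maps are typically proprietary, the package
ships a first-class **synthetic-data module** that generates landscapes,
weather, and GPS tracks with *known* selection coefficients, so every
estimator can be exercised end-to-end and checked for parameter recovery.

## The analysis

**Landscape scale (2nd-order selection).** Availability is the herd's
seasonal range — the 95% isopleth of a Gaussian kernel density estimate of
the season's fixes, with the ad hoc (normal-reference) bandwidth
h = σ̂·n^(−1/6) per axis. One random available point is drawn per used
point, uniform over the range excluding water, and selection is estimated
with a logistic mixed model with crossed random intercepts for animal and
year (Laplace approximation, matching glmer's default):

    logit P(used) = β₀ + Σᵢ βᵢ xᵢ + u_animal + u_year

**Patch scale (step selection).** For each used location, five matched
available locations are generated by resampling (with replacement)
movement rates and bearings from that animal's own steps in the season,
displacing from the previous fix. Each used point plus its five matches
forms one stratum of a conditional logistic regression,

    L(β) = Σ_strata [ βᵀx_used − log Σⱼ exp(βᵀxⱼ) ],

maximized by Newton–Raphson to gradient norm < 1e-8. Serial
autocorrelation is handled by summing deviance residuals per stratum,
measuring the residual correlation lag with an ACF rule, splitting strata
into two lag-spaced interleaved groups, refitting on each, and averaging
the two covariance matrices (robust SEs; coefficients are called
significant when the 95% CI β ± 1.96·SE_robust excludes zero).

**Covariates.** Nine-class tundra vegetation (sedge–grass meadow as the
reference class), per-class vegetation *density* in moving windows sized
by the scale of maximum patchiness (three-term local quadrat variance,
TTLQV), NDVI phenology dates (green-up, maximum growth, senescence, with
the 0.1 growing-season threshold), terrain ruggedness (vector ruggedness
measure, VRM, 8-pixel window), distance to coastline, and precipitation.
Elevation and distance to coast are log-transformed, ruggedness
square-root-transformed, everything z-standardized on the fitting sample,
and collinearity is pruned by iteratively dropping the highest VIF until
all VIF < 3.

**Insect harassment.** Mosquito and oestrid-fly activity indices from
temperature and wind (bilinear ramps anchored at the published corner
conditions: maximal above 18 °C at calm wind; zero below 6 °C / above
6 m/s for mosquitoes, below 13 °C / above 9 m/s for flies). A location
falls in a *high*-harassment period when the index exceeds 0.5 at either
weather station within the preceding 12 hours.

**Validation and mapping.** Animal-partitioned k-fold cross-validation
(withheld used points tallied across equal-area RSF-score bins; Spearman
ρ̄ of bin rank vs area-adjusted frequency), and prediction surfaces
w(x) = exp(β₀+Σβᵢxᵢ)/(1+exp(β₀+Σβᵢxᵢ)) with water masked as no-data.

## Worked example

The bundled demo simulates a full summer of 2-hourly GPS data for eight
collared females on a 160×160-cell synthetic tundra mosaic (30 m cells),
with true step-selection coefficients
`{sedge_grass_meadow: +1.0, wet_tundra: −0.6, dist_coast: −0.4}`,
then runs the entire analysis:

```bash
rsf demo --seed 1 --out demo_run
# or: python -c "from caribou_rsf.pipeline import run_demo; run_demo('demo_run', seed=1)"
```

From `demo_run/results/manifest.json` (seed 1):

* Screening removed 2.58% of 10,280 raw fixes (the generator injects 2.6%
  bad fixes: 2D and PDOP > 10), and the 25 m sedentary filter a further
  ~1.4%, leaving 9,874 fixes.
* Post-calving, landscape scale (mixed logistic, random intercepts for
  animal and year; animal SD 0.16): strong avoidance of wet, flooded
  patches (`patch_wet_tundra` −1.56, `patch_flooded` −0.61) and selection
  toward the coast (`dist_coast` −0.46) — the signs the simulation's truth
  implies at this scale.
* Post-calving, patch scale (conditional logistic over 1-used/5-available
  strata, residual lag 2, robust SEs): `patch_wet_tundra` −1.32 ± 0.32
  (significant), `dist_coast` −0.28 ± 0.11 (significant), `vrm` 0.03 ±
  0.05 (not significant — ruggedness carries no true effect).
* k-fold validation (5 folds by animal, 10 bins): ρ̄ = 0.56, P = 0.003 at
  the landscape scale for post-calving.
* Per-season relative-probability-of-use surfaces are written as
  `w_<season>.asc` (float w(x) in [0,1], water = no-data) plus a
  decile-classed variant.

The same machinery runs on real data via a YAML config:

```bash
rsf run --config run.yaml   # paths to fixes.csv, weather.csv, stack/, thresholds, seed
```

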