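# Methods

This note documents the models, conventions and design choices behind
`wolfmove`, in the spirit of a package vignette: what is computed, under
which assumptions, with which defaults, and what the synthetic validation
does and does not establish.

## Daily tracks and movement metrics

A *daily track* runs from 16:00 of day D to 14:00 of day D+1, bracketing
the main resting periods of the study system; at a 2-h fix cadence it has
12 expected slots (16, 18, …, 12, 14 h).  A fix is matched to a slot when
it falls within ±30 min of the nominal time (collar jitter tolerance,
configurable); fixes in the 14:00–16:00 gap belong to no track.  Tracks
with more than one missing slot (completeness ≤ 90%) are dropped, and the
drop count is always reported.

* **Daily distance** — sum of Euclidean steps between consecutive
  *observed* fixes.  A single missing interior fix therefore bridges a 4-h
  step with no interpolation: with at most one missing slot this
  underestimates distance only slightly, and it is the minimal assumption.
* **Net displacement** — distance between the first and last observed fix.
* **Straightness** — net/daily.  When daily distance is exactly 0 the ratio
  is 0/0; the value is left undefined (NaN) and excluded from the
  straightness model rather than imputed.

Summary tables report mean, median, SD, min, max, Q1, Q3 and IQR; quantiles
use linear interpolation (numpy default), which must be fixed for the
table to be reproducible.

All geometry in the package is planar Euclidean in kilometres.  Real data
must be projected before use; no geodesic computations are performed.

## Influence areas and covariates

Covariates are averaged inside the 1-km buffer of each track's polyline
(≈ the mean step length, so the buffer represents the day's experienced
surroundings).  Rasters are averaged over cells whose centers fall inside
the polygon.

* **Settlement surfaces** — quartic (biweight) kernel density
  K(d) = 3/(πh²)(1 − d²/h²)², with bandwidth h = 1 km by default (the
  source GIS workflow names the tool but not the bandwidth; it is
  configurable).  Weighted by settlement population for the
  population-density surface and unweighted for settlement density; a raw
  count-per-buffer variant is also emitted since the original choice is
  ambiguous.
* **Road density** — clipped length of each class inside the polygon ÷
  polygon area (km/km²).
* **TRI** — Riley convention: per cell, √Σ(z − z_neighbor)² over the 8
  neighbors, edge cells using the neighbors they have; per track, the mean
  over cells in the influence area.
* **Refuge metrics** — on the 10-m binary refuge raster clipped to the
  influence area (clipping keeps the metric local; a whole-patch variant
  would mix in conditions far from the track):
  - patches are 8-connected components (FRAGSTATS-style default;
    configurable);
  - % cover, patch density (patches/km²), mean patch size (km²);
  - per-patch fractal dimension FDI = 2·ln(0.25P)/ln(A) in cell units,
    defined as 1 for single cells and clipped to [1, 2] with the clip count
    reported (the discrete formula cannot exceed 2: maximum perimeter is
    4A, which gives exactly 2);
  - patch cohesion by the FRAGSTATS formula
    (1 − Σp/Σp√a)·(1 − 1/√Z)⁻¹ with p, a in cell units and Z the number of
    cells in the influence area, reported on [0, 1] (the conventional
    value ÷ 100).  A stated range of [−1, 1] for this index circulates in
    the literature but does not correspond to any standard cohesion
    formula; the [0, 1] convention is used here and, because predictors
    are standardized before modeling, the choice does not affect the fits.

The five refuge metrics are strongly correlated, so the models use the
first two principal components of their correlation matrix.  Zero-patch
areas are imputed at limiting values (size 0, cohesion 0, FDI 1) to stay
in the analysis.  Signs are fixed so dim1 loads positively on % cover
(extent/cohesion axis) and dim2 positively on FDI (shape-complexity axis).
On synthetic landscapes this reproduces the familiar structure: dim1 ≈ 67%
of variance separating extensive/cohesive from fragmented cover, dim2 ≈
15–17% separating complex from geometric patch shapes.

## Models

One comprehensive model per movement metric, structure fixed a priori (no
model selection):

* daily distance and net displacement: Gaussian errors on the √ scale (the
  transformation that makes residuals approximately normal for these
  right-skewed distances);
* straightness: zero-inflated Beta — P(S = 0) = π, and S | S > 0 ~
  Beta(μφ, (1−μ)φ) with logit(μ) the linear predictor.  Exact 1s (possible
  in principle for a perfectly straight day) are compressed by
  y′ = (y(n−1) + 0.5)/n applied only to boundary values, since the Beta
  excludes 1.

Fixed effects: age (subadult/adult), sex, social status (pack/nonpack),
reproductive period (mating Feb–Apr, breeding May–Oct, nonreproductive
Nov–Jan — assigned from the track's calendar month), diet category
(wild/livestock/horses), population density, settlement density, primary
and secondary road density, TRI, refuge dim1 and dim2; interactions
sex×period, status×period, population×settlement, each road class × each
refuge dimension, and dim1×dim2.  Categorical terms use treatment coding
with references subadult/female/pack/mating/wild.  Continuous predictors
are standardized (mean 0, SD 1) at fit time; the stored training
means/SDs are reused for all predictions.

Random intercepts: individual, and the 1×1-km grid cell containing the
track's mid-coordinates (mean of its fixes) — the fine-scale spatial
effect.  A random effect observed at fewer than two levels is dropped (a
one-level intercept is not identifiable beside the global intercept).
Random slopes are deliberately not supported.

Priors: Normal(0, 10) intercept, Normal(0, 1) slopes.  The SD and
precision priors are not dictated by the source workflow; the package uses
Half-Normal(2.5) for σ_ind, σ_cell, σ_resid (a weakly-informative scale in
the brms tradition) and Normal(log 10, 1.5) on log φ.

To break day-to-day serial dependence the modeling data are a stratified
random two-thirds subsample: ⌊2n/3⌋ per individual × calendar-month
stratum, floor rule (a one-row stratum keeps nothing), deterministic under
its seed.

### Posterior computation

Posteriors are sampled with a compact Hamiltonian Monte Carlo
implementation written for this package: analytic gradients for both
likelihoods (verified against finite differences in the test suite),
non-centered parameterization of the random effects, dual-averaging step
size targeting 0.85 acceptance, a diagonal mass matrix estimated from a
mid-warmup window with shrinkage toward unit scale, jittered leapfrog
path lengths, and a divergence guard.  A chain whose sampling-phase
acceptance collapses (a rare adaptation failure) is discarded and rerun
from a fresh jittered start.  The zero-inflation probability π has an
exact Beta(1 + n₀, 1 + n₊) conjugate posterior and is drawn directly.

Reference settings are 4 chains × 4,000 iterations (2,000 warmup);
development and test fits use 2 chains × 1,000 post-warmup draws, which on
the simulation sizes below keeps split-R-hat ≲ 1.02 for all reported
parameters.  Convergence is operationalized as R-hat < 1.01 at reference
settings (an "R-hat ≈ 1" requirement is not testable verbatim).

Predictions are medians over draws of the conditional expectation: the
squared linear predictor for the Gaussian models (natural scale; the
√-scale prediction is also exposed, and whether pseudo-R² should be
computed before or after back-transformation is genuinely ambiguous — the
natural scale is the default) and (1 − π)μ for the zero-inflated Beta.  A
novel random-effect level predicts at the population level (effect 0).

## Variable importance

PD is the posterior mass of the dominant sign (range [0.5, 1], with
PD > 0.9 a credible direction and a 95% CI excluding zero the significance
rule — the two are mutually consistent: an excluded zero implies
PD > 0.975).  Pseudo-R² is the squared Pearson correlation between
observed responses and median predictions.

Variance partitioning neutralizes one predictor at a time: continuous →
held at its mean (0 standardized); categorical → all rows set to each
level in turn, drops averaged (unweighted by default; a
frequency-weighted option exists since the original convention is
unstated); interactions → their design columns held at the training mean;
random effects → every level replaced by a novel one.  Interaction columns
are *recomputed* when a parent main effect is neutralized, keeping the
design internally consistent.  Drops are reported raw (they can be
slightly negative by chance) and floored at zero for the percentage
columns; the drops are not an exact decomposition and their sum can exceed
the baseline when predictors are correlated.

Marginal-effect grids hold non-focal continuous terms at their mean,
categoricals at reference, random effects at the population level, and
evaluate interaction moderators at their observed Q1/Q3.

## Diagnostics

Residuals are taken on the fitting scale (√ for the distance models).
Temporal: within-individual ACF at day lags, where days removed by the
subsample break lag chains (pairs are formed only between days actually
present, never bridged).  The reported white-noise expectation of the
lag-k estimate is ≈ −1/n (Anderson's small-sample bias); significance
checks should center there.  Spatial: Moran's I over track midpoints with
inverse-distance weights cut off at 5 km (the test is standard; the weight
rule is a package default, configurable), with the normality-based
expectation −1/(n−1), variance, z and p.  Posterior predictive checks
simulate replicate response vectors from posterior draws and compare
observed mean, SD and (for straightness) the zero fraction against the
replicate distributions via tail probabilities.

## The synthetic generator

The generator emulates the study conditions, not a particular dataset:

* **Landscape** (10-m rasters): refuge = smoothed Gaussian noise
  thresholded at the quantile giving the target cover (default 50%,
  patchiness length 200 m — patches spanning both PCA axes); elevation =
  broad-scale smoothed noise over a 400-m relief; settlements = 3/km²
  uniform points with lognormal(3, 1.2) populations (heavy-tailed sizes);
  roads = random clipped segments accumulated to exactly 0.5 (primary) and
  3.0 (secondary) km/km² — together the ~3.5 km/km² of the study region.
  Infeasible targets fail loudly rather than silently under-building.
* **Tracks**: 2-h fixes in the 16:00→14:00 window.  Each day, standardized
  1-km-disk covariate surfaces are read at the day's start position, the
  linear predictor η is formed with the day's individual and grid-cell
  intercepts, √D is drawn from Normal(η, σ_resid) (floored at 0.15 √km),
  and a correlated random walk of 11 gamma-weighted steps is scaled so the
  realized daily distance equals D exactly (steps are capped at 45% of the
  extent and redistributed so every step fits; headings are redrawn rather
  than truncated at the boundary, preserving lengths).  Day-level control
  is what makes the truth exactly recoverable by a daily-aggregate
  pipeline.  A home-attraction term keeps individuals territory-bound.
  With probability π a day is closed into a loop, producing exact
  straightness zeros.  Fixes are then dropped independently at the
  missingness rate.  Defaults: 26 individuals, 52–397 days each, 2%
  missingness; intercept 3.0 √km and σ_resid 0.8, calibrated so the
  emergent metrics land at the observed magnitudes (~9 km mean daily
  distance, steps ≈ 0.8 ± 1.2 km).
* The generator's two refuge covariate surfaces (disk-mean cover; local
  edge density) are its *own* standardized axes; the pipeline's PCA
  dimensions estimated from extracted patch metrics correlate with but do
  not equal them.  Recovery tests therefore fit on the generator's
  realized covariates (re-standardization disabled), which is exactly the
  scale on which the truth is defined; end-to-end runs through extraction
  are checked qualitatively (signs, significance of planted effects).

What passing tests show: the estimators agree with independent brute-force
oracles; the samplers recover known coefficients, SDs and zero-inflation
with calibrated intervals; the partition ranks dominant/null/random
contributions correctly; the diagnostics hold their nominal error rates.
What they do not show: behavioral realism (no territoriality beyond home
attraction, no activity cycles, no road-crossing behavior, no collar
error), and nothing about any particular real dataset.

## Validation problem sizes

Chosen to exercise each property at desk scale: metric oracles on 1,000
random tracks; landscape oracles on 200 random 20×20 rasters; Gaussian
recovery on 5 replicates of 20 individuals × 150 days (≈ 2,000 modeled
days after subsampling) at 2 × 1,000 reduced MCMC; zero-inflated Beta
recovery at n = 2,000; partition validity at 15 × 100 days; filter
bookkeeping at 800 days with 5% missingness; diagnostic calibration over
200 white-noise replicates.  In the recovery scenario the diet effect is
deliberately modest (−0.25): individual-level attributes are informed by
only 20 individuals, so only day-level effects are placed in the
strong-effect range that the design can detect with PD > 0.9.

## Known limitations

* The movement simulator is a validation instrument, not an ecological
  model; its correlated random walk has no behavioral states.
* Variance-partition percentages are not additive across correlated
  predictors.
* The HMC sampler is tuned for these smooth hierarchical posteriors; it is
  not a general-purpose replacement for a probabilistic-programming
  framework (no NUTS tree doubling, diagonal metric only).
* Covariate extraction cost grows with buffer area × raster resolution;
  very long daily tracks on 10-m rasters are the slow path.
* Fits are serialized as compressed .npz with embedded JSON rather than a
  NetCDF posterior file; `PosteriorFit.to_inference_data()` exposes the
  draws to the ArviZ ecosystem in memory.
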