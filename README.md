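# wolfmove

Daily movement analysis for GPS-collared top predators in human-dominated
landscapes: trajectory metrics, landscape covariates, Bayesian hierarchical
models, and predictive variance partitioning — with a synthetic generator
that makes the whole pipeline testable end to end when the underlying
telemetry cannot be shared (locations of a protected species).

## The scientific problem

How do intrinsic traits (sex, age, social status, reproductive period),
anthropogenic disturbance (human population and settlement density, paved
roads), terrain, prey type, and the extent and configuration of refuge
vegetation jointly shape the *daily* movements of a large carnivore living
among people?  The package operationalizes that question for 2-h GPS
telemetry of wolves (or any comparable top predator):

1. **Daily tracks.** Fixes are segmented into 16:00 → 14:00 windows (12
   expected fixes); tracks with more than one missing fix (>90%
   completeness rule) are discarded.  Three metrics per track:
   daily distance `D = Σ step lengths`, net displacement
   `N = ‖x_last − x_first‖`, and straightness `S = N / D ∈ [0, 1]`.
2. **Influence areas.** Each track is buffered by 1 km and covariates are
   averaged inside: quartic-kernel densities of population-weighted
   settlements, road length density per class (primary/secondary), mean
   terrain ruggedness (Riley TRI), and five refuge pattern metrics
   (% cover, patch density, mean patch size, patch cohesion, fractal
   dimension), reduced by PCA to two refuge dimensions.
3. **Models.** One comprehensive Bayesian regression per metric:

   ```
   √D_i ~ Normal(μ_i, σ)            (same for √N)
   S_i  ~ ZIBeta(π, μ_i, φ)         (point mass at 0 + Beta on (0,1), logit link)
   μ_i  = β₀ + x_iᵀβ + a_{ind(i)} + b_{cell(i)}
   a_j ~ Normal(0, σ_ind),  b_k ~ Normal(0, σ_cell)
   β₀ ~ Normal(0, 10),  β ~ Normal(0, 1),  σ ~ Half-Normal(2.5)
   ```

   with fixed effects for all predictors plus a-priori interactions
   (sex×period, status×period, population×settlement, roads×refuge
   dimensions, refuge dim1×dim2), random intercepts for the individual and
   the 1×1-km grid cell of the track midpoint, and continuous predictors
   standardized.  Posteriors are sampled by Hamiltonian Monte Carlo
   (non-centered random effects; the zero-inflation probability has an
   exact conjugate Beta posterior).
4. **Importance.** Probability of Direction (PD) and 95% credible intervals
   per coefficient; predictive pseudo-R² = squared correlation between
   observed responses and median posterior predictions; each predictor's
   importance is the pseudo-R² drop when it is neutralized (continuous →
   mean, categorical → each level in turn, random effect → novel level),
   expressed as % of baseline.
5. **Diagnostics.** Within-individual residual ACF over day lags, Moran's I
   over track midpoints, posterior predictive checks, R-hat.

Because the real telemetry is legally restricted, the package ships a
first-class synthetic module: landscapes with settlement, road, terrain and
refuge structure matching the study region's densities, and a
correlated-random-walk simulator whose expected √(daily distance) follows a
known linear predictor — so coefficient recovery, variance-partition
behavior and diagnostic calibration are all verifiable against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs under `results/analysis/`):

```bash
python analysis/01_simulate.py        # landscape + 10 wolves x 60 days of 2-h fixes
python analysis/02_daily_metrics.py   # daily tracks, completeness filter, metrics
python analysis/03_covariates.py      # 1-km influence areas, covariates, refuge PCA
python analysis/04_fit_models.py      # three hierarchical fits (reduced MCMC)
python analysis/05_importance.py      # PD tables + variance partitioning
python analysis/06_diagnostics.py     # ACF, Moran's I, PPC, R-hat
```

Stage 2 prints the metric summary (km; straightness unitless):

```
                     mean  median    sd   min    max    q1     q3   iqr
daily_distance_km    9.55    8.04  7.18  0.02  42.74  4.05  13.54  9.50
net_displacement_km  2.66    2.44  1.69  0.00   8.72  1.36   3.73  2.36
straightness         0.41    0.35  0.27  0.00   0.99  0.19   0.62  0.43
```

i.e. simulated wolves travel ~9.5 km per day but end up only ~2.7 km from
where they started — tortuous, territory-bound movement.  Stage 3 reduces
the five refuge metrics to two PCA axes (67% + 17% of variance; dim1 loads
positively on cover/cohesion/patch size and negatively on patch density,
dim2 on fractal dimension).  Stage 4 reports, for the daily-distance model,
`max R-hat 1.013` and recovers exactly the planted effects as significant
(settlement, population, roads, TRI negative; refuge dim1 positive;
population×settlement and primary-road×refuge-dim1 interactions).  Stage 5
partitions the explained variance — e.g. settlement density and the
grid-cell spatial effect emerge as the top contributors for daily distance
— and stage 6 confirms flat residual ACF (+0.006 at lag 1), non-significant
Moran's I (p = 0.42), and posterior predictive tail probabilities well
inside (0.05, 0.95).

The same pipeline runs from one config with the `wolfmove` CLI
(`wolfmove all --config cfg.yaml`, or `wolfmove demo` for a self-contained
run); real fix tables can be supplied as CSV with pre-projected planar
km coordinates.

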