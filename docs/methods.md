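# Methods

This note documents the statistical content of the package: the models
and procedures, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
decisions that affect results.

## Population-weighted exposure

For a region *p* and an aligned value raster *X* and population raster
*pop*, the exposure is `Σ_i w_ip X_ip` with `w_ip = pop_ip / Σ_i pop_ip`,
the sum running over the region's cells. Conventions:

- A cell that is nodata in *either* raster is removed from both the
  numerator and the weight sum (weights renormalise over valid cells).
- A region with zero valid population gets NaN plus a logged warning.
  Fabricating a 0 would silently misclassify the region downstream.
- No CRS handling, reprojection or resampling: rasters must already
  share one grid. On-disk format is the ESRI ASCII grid, written with
  full-precision floats so round trips are bit-exact.

The weighted mean is invariant to uniform rescaling of population and is
bounded by the within-region value range; both are property-tested, and
the implementation is checked against a per-pixel loop oracle at 1e-12.

## Stratification

Defaults (all configurable):

| axis | variable | cuts | classes |
|---|---|---|---|
| environment type | population-weighted elevation (m) | 300, 950 | I / II / III |
| development stage | urbanization rate (%) | 30, 70 | 1 / 2 / 3 |

Boundary values belong to the **middle** class (300 m → II, 70% → 2);
the printed ranges "300–950" and "30–70" read as inclusive, and some
convention is mandatory for a deterministic classifier. Environment type
is computed once per region (base-year population weights) and held
fixed across years; terrain does not move, and recomputing it per census
year would let population redistribution silently re-type a region.

`jenks_breaks` is an exact Fisher–Jenks classifier: dynamic programming
over contiguous partitions of the sorted values, minimising total
within-class sum of squared deviations, O(k n²) with prefix sums. It is
not the common greedy/heuristic variant; tests compare it against
exhaustive enumeration of all partitions for n ≤ 12. Cost ties are
broken toward smaller split indices, deterministically. The `jenks`
stratification mode classifies by the optimal partition directly and
exists to show how threshold sets like 300/950 arise from data; the
fixed rules remain the authoritative default because the two coexist in
practice without a reconciliation rule.

## Geodetector q-statistic

`q = 1 − Σ_h N_h σ²_h / (N σ²)` over strata h = 1..L. Variances use the
population (divide-by-N) convention so that `N_h σ²_h` is exactly the
within-stratum sum of squares and `q = 1 − SSW/SST` holds identically
for unbalanced strata — with sample variances the identity fails.
Singleton strata contribute zero within-stratum variance. A constant
outcome makes q undefined (0/0) and raises, rather than returning 0 or
1; in per-year tables the cell becomes NaN with a warning. q is
invariant to affine transforms of the outcome and can only rise under
refinement of the stratification; both are property-tested against an
independent loop oracle. No significance test is attached — only the
point statistic is in scope.

## The multilevel model

Response: region-year LE. Fixed effects: an intercept plus selected
covariates (default: GDP per capita in 10k currency units, mean years of
schooling, out-of-pocket health-spending share %, gross dependency ratio
%, sex ratio). Random part: crossed intercepts for environment type and
development stage plus i.i.d. residual,

    V = σ²_t Z_t Z_t' + σ²_s Z_s Z_s' + σ²_e I.

**Estimation.** REML with β profiled out by GLS. The variance components
are optimised on the log scale (L-BFGS-B within [e⁻²³, e²³], Nelder–Mead
rescue; a component at the lower bound is reported as exactly 0 and the
published fit is recomputed at the reported values, so the GLS identity
holds at the printed V). All solves use the Woodbury identity, making an
objective evaluation O(n q²) for q total group levels. When the true
residual variance is 0 the restricted likelihood is flat along the
collapsed direction and formal optimizer convergence criteria can fail;
the fit is then accepted iff a coordinate probe confirms a local
minimum, which is also an invariant of every returned fit.

**Identifiability caveat.** With the real-world 3 × 3 design the
variance components are estimated from 3 realized effects per factor and
are intrinsically noisy — even an oracle observing the effects directly
has ~50%+ median relative error at 3 levels, and ~30% at 10 levels.
Recovery simulations therefore use enlarged designs (10 × 10 levels) and
test median bias of the estimator rather than per-replicate error; the
documentation of any 3 × 3 fit should treat σ̂²_t, σ̂²_s as rough.

**Stepwise selection.** Forward–backward search over candidate
covariates, scored on ML (not REML) fits — REML criteria are not
comparable across fixed-effect sets. Default criterion AIC, with BIC
available. A known property worth stating: AIC admits a null covariate
with probability ≈ P(χ²₁ > 2) ≈ 0.16, so *exact* support recovery under
AIC plateaus near 36% with six nulls; the consistent BIC variant is the
one that recovers the exact support ≥ 80% of the time in simulation.
The selection trace (every accepted add/drop with its score) is
returned and logged.

**Prediction.** Point prediction `x'β̂ + û_t + û_s` with BLUPs
`û = D Z' V⁻¹ (y − Xβ̂)`. The default interval uses the full joint
prediction-error variance

    var = x'Aβ x + m'C_uu m + 2 x'C_bu m,
    Aβ = (X'V⁻¹X)⁻¹,  C_uu = D − D Z'P Z D,  C_bu = −Aβ X'V⁻¹ Z D,

with `P = V⁻¹ − V⁻¹X Aβ X'V⁻¹`. The cross term C_bu is not negligible:
dropping it (the `additive` mode, kept for comparison) systematically
over-covers in simulation (≈100% observed vs 96.5% for the joint form at
nominal 95%). Intervals are for the *expected* LE of a region in known
groups; `new_observation` mode adds σ²_e. A row naming an unseen group
level falls back to fixed-effects-only prediction with the full prior
variance of that effect added to the interval, and a warning.

**Cross-validation.** Folds are groups of regions (default
leave-one-region-out), so a region's own years never inform its
prediction. Held-out rows are predicted with BLUPs estimated from the
training fold; a (type, stage) level absent from training triggers the
fixed-only fallback, logged. The comparator is pooled OLS on the same
covariates; metrics are out-of-fold RMSE and MAE. Fold assignment
depends only on the sorted region ids and the seed, so it is invariant
to row order.

## Projection and inequality

Scenario rows carry the model covariates for the target year. Stages are
reclassified from scenario urbanization *before* prediction (the stage
BLUP switches accordingly); environment types carry over. National LE is
the population-weighted mean of regional predictions — an unweighted
mean would be inconsistent with how national LE is constructed from
provincial populations — with variance `Σ w²_i var_i` under cross-region
independence of prediction errors. That independence is a simplification
(shared fixed-effect uncertainty correlates regions); it narrows the
national interval and is flagged here deliberately.

Inequality is reported as a four-metric panel, because "inequality"
alone underdetermines the statistic: range, population-weighted SD,
CV = SD/weighted mean, and the population-weighted Gini
`ΣΣ w_i w_j |x_i − x_j| / (2 μ_w)`. CV and Gini are scale-invariant; all
four are invariant to weight normalisation and permutation. Decadal
growth is `LE(t+10) − LE(t)` and `100·(LE(t+10) − LE(t))/LE(t)` per
region or for the national series; missing decade endpoints raise rather
than interpolate.

## Synthetic world

The generator emulates the *statistical* structure the analysis assumes,
not any real geography:

- **Rasters**: zones are a Voronoi partition of the grid (contiguous by
  construction) with ≥ 4 cells per region; per-region elevations are
  drawn inside the assigned type's classification band (so the
  population-weighted mean provably lands in the intended class);
  population is gamma-distributed and strictly positive, dense on
  low-elevation regions and sparse on the plateau type.
- **Panel**: 31 regions × 2000/2010/2020 by default. Covariates start
  uniform in declared ranges and drift linearly per decade (development:
  urbanization +14 points/decade spans all three stages across the study
  window; out-of-pocket share and dependency fall; schooling and GDP
  rise). The ranges and drifts are conventions chosen to look like a
  rapidly developing middle-income country; no source prescribes exact
  distributions. LE is generated *exactly* as
  `x'β + u_t + u_s + e`, with β₀ = 75 and the five active coefficients
  above; urbanization, physician density, elevation exposure and
  calendar year are carried as genuine null candidates for the
  selector. Default variance truth (σ²_t, σ²_s, σ²_e) = (1.0, 0.5,
  0.25).
- **Scenario**: continues each covariate's per-decade drift to the
  target year, clips urbanization to [0, 100], recomputes stages, grows
  population 5%/decade.
- **Reproducibility**: every artifact is a deterministic function of one
  seed; realized group effects are recorded in a truth JSON so recovery
  tests compare estimates to truth, not to other estimates.

Not emulated: spatial autocorrelation of outcomes, covariate measurement
error, demographic cohort structure, real scenario-database
trajectories, real administrative boundaries. A green test establishes
that the chain recovers the structure it assumes — it says nothing about
how well that structure describes any particular country's data.

## Numerical conventions

- Variance-component floor 1e-10; components below 1e-8 × var(y) are
  reported as exactly 0.
- Jenks and REML tie-breaks are deterministic (documented above), so
  every pipeline stage is order-invariant and bit-reproducible; CSV/JSON
  artifacts are written with fixed float formatting and sorted keys, and
  the pipeline manifest records SHA-256 checksums of every output.
- LE outside (30, 100) years, urbanization outside [0, 100] and
  duplicate (region, year) keys are schema errors at I/O time, reported
  with row numbers.

## Known limitations

- Variance components from a 3 × 3 grouping design are weakly
  identified (above); treat them as descriptive.
- The national interval ignores cross-region error correlation.
- The q-statistic is reported without a significance test.
- Newick export encodes LE in leaf names (two decimals); the JSON
  document is the lossless canonical form.
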