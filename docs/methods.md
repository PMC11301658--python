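# Methods

This note documents the models implemented in `scalesdm`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Detection functions and effort

Perpendicular distances come from the survey geometry
`d = altitude / tan(declination)`, declination measured from the horizontal
in (0°, 90°]; the default platform is an aerial survey at 183 m altitude
and 167 km/h with a 500 m search half-strip and no further truncation of
extreme distances inside it.

Two keys are fitted by maximising the line-transect likelihood
`Π g(xᵢ)/∫₀ʷ g`: half-normal (`σ`) and hazard-rate (`σ`, shape `b ≥ 1`,
enforced via a `log(b−1)` parameterisation so the key keeps a shoulder and
is monotone non-increasing). The integral `∫₀ʷ g` uses 64-node
Gauss–Legendre quadrature — for these smooth monotone integrands that is
accurate far beyond the 1e−6 relative agreement we verify against the
half-normal closed form `σ√(π/2)·erf(w/(σ√2))`. One sighting-condition
covariate at a time may enter the scale, `σᵢ = exp(β₀ + β₁zᵢ)` (several at
once are not supported: detection datasets in this setting are small). The
covariate is retained only when it lowers AIC by more than two units.
Detection functions are fitted per survey year.

Goodness of fit is the Cramér–von Mises statistic of the empirical versus
fitted distance CDF with the standard asymptotic p-value; below 50
observations a parametric bootstrap (199 resamples from the fitted density)
replaces the asymptotic approximation. A fit whose scale collapses toward
zero (e.g. all distances equal) is reported as a degenerate-fit error
rather than returned.

## Grid dataset

The analysis grid is 4 km × 4 km on a planar km coordinate system (no
geodesy; real data must arrive pre-projected). Cell membership is half-open
(`[x₀, x₀+4) × [y₀, y₀+4)`), so boundary points belong to exactly one cell
and counts are conserved. Each track segment is split analytically at cell
boundaries; its searched area is `length × 2·ESW`, or `length × ESW` when
only one side of the platform was observed. Total searched area is
invariant to the grid origin (verified to 0.1%). Presence is 1 iff at
least one sighting fell in the cell that year; a cell surveyed in two years
contributes two rows, with year as a categorical model term. "Effort" in
the models is the searched area in km²; depth is the bathymetry value at
the cell centroid, in positive metres below sea level.

## Multi-scale covariates

Spatial levels 5, 20 and 40 km come from origin-anchored block means
(factors 4 and 8 for a ~5 km source, 3 and 6 for a ~7 km source, whose
native grid stands in for the 5-km level); partial edge blocks average the
cells available, and an all-missing block stays missing. Temporal levels
are the cellwise mean of available daily layers per calendar month and over
the whole survey period. On complete rasters the two operators commute
exactly (both are means), and across-cell variance is non-increasing in the
aggregation factor.

The thermal-front index is Horn's 3×3 weighted finite-difference gradient
magnitude of SST, reported per km so it is comparable across spatial
levels; edges use nearest-neighbour padding and missing neighbours
propagate. The kernel is exact on planar fields, which the tests exploit.

Cells take the value of the aggregated/composited raster cell containing
their centroid. A cell surveyed on several days uses the effort-weighted
mean across its dates at the daily (and monthly) level; the survey-period
level is date-independent. Rows with any missing value are excluded *per
covariate*, so each variable has its own dataset and its own base-model
comparison — base-model statistics legitimately differ between covariates.
CHLA and MLD are log-transformed (rows with non-positive values excluded
and counted); every covariate plus depth and effort is then standardised
(sample sd) over the retained rows, after exclusion.

## The binary shrinkage GAM

Model: `logit P(Y=1) = β₀ + β₁·year + f(effort) + f(depth) [+ f(X)]`.
Each smooth uses a rank-`k` (default 10) thin-plate-style basis: cubic
radial functions `|x − κⱼ|³` at quantile knots with the thin-plate side
conditions absorbed by a QR reparameterisation, plus the linear column;
columns are centred over the data (sum-to-zero identifiability) and scaled
to unit RMS, with penalties transformed accordingly and the wiggliness
penalty Frobenius-normalised so smoothing parameters are comparable across
terms. Shrinkage is the double-penalty construction: a second ridge penalty
on the penalty null space (the linear direction), so selection can drive a
whole term to EDF ≈ 0.

Fitting is penalised IRLS (step-halving on the penalised deviance,
convergence at relative deviance change < 1e−8, hard cap 200 iterations).
Smoothing parameters minimise a UBRE-type criterion in which the model
degrees of freedom are multiplied by γ = 1.4 to discourage overfit
wiggliness. The search is coordinate-wise golden-section on log λ over
[e⁻⁸, e¹⁸]: two performance-iteration cycles against the working
least-squares criterion (cheap: each evaluation is a p×p solve), then one
refinement cycle against the exact criterion `(deviance + 2γ·EDF)/n`
evaluated at converged warm-started fits. The procedure is deterministic.
EDF is the trace of the influence matrix, partitioned over terms by its
diagonal; `AIC = −2ℓ + 2·EDF` (the γ factor affects smoothness selection
only, not AIC, matching standard practice). On identical data this engine
reproduces the reference shrinkage-GAM implementation in R (mgcv, `bs="ts"`,
γ = 1.4) almost seed-for-seed in per-term EDFs and fitted probabilities —
the test suite includes that cross-check.

Smooth-term p-values are Wald-type: `βⱼᵀ Vⱼ⁻ βⱼ` with the Bayesian
posterior covariance block pseudo-inverted and a χ² reference on the
rounded per-term EDF. They are approximate, as all penalised-smooth
p-values are, and are flagged as such. Partial effects are the centred
smooth on a grid with pointwise ±1.96·SE bands from the posterior
covariance; simulation shows ~94% average pointwise coverage for a linear
truth — the classical "across-the-function" property, which holds on
average over replicates, not for every dataset.

## Scale selection and diagnostics

For each covariate: fit the base model on that covariate's dataset, then
the 9 candidates `base + f(X at scale)` labelled `<var><km><d|m|p>`;
rank by AIC; report every candidate within 2 AIC units of the best as a
tie. Exact AIC ties break deterministically toward the coarser temporal,
then coarser spatial, scale (the full tie set is always reported, which is
the scientifically meaningful output). VIF is computed on observed
covariate values via OLS R² (≥ 2 flagged); concurvity is the proportion of
a smooth's fitted-component variance explainable by projection onto the
other model terms' column space, in [0, 1] (> 0.8 flagged; a single smooth
scores 0 by convention). Selection is deterministic given data and
configuration.

## Validation

AUC is the normalised Mann–Whitney statistic (ties counted half), which
equals the trapezoidal area under the empirical ROC exactly. The
classification threshold maximises sensitivity + specificity per held-out
fold of a seeded stratified 5-fold split and is averaged over folds; ties
resolve toward the higher cut, and the returned value is the midpoint
between the chosen cut and the next score below it, so it lies inside
separating gaps. Confusion matrices are computed in-sample at that
threshold.

## The synthetic world

Fields are stationary Gaussian random fields with exponential covariance
(e-folding `range_km`), sampled exactly by circulant embedding (padded
torus, FFT spectrum; negative spectral mass, when any, is clipped and is
zero at the default settings). Day-to-day evolution is AR(1) on the
anomaly, so every day is marginally correct and the lag-1 autocorrelation
equals the coefficient; a linear seasonal trend can be added. Defaults
emulate a summer shelf-sea SST product: mean 13 °C, sd 1 °C, 15 km spatial
range, AR(1) 0.8, +0.02 °C/day over a 61-day (June–July) season, on a
200 km × 200 km domain at 5 km resolution, for three survey years.

Transects are equally spaced zig-zags (or parallel lines) clipped to
strata, chopped into ≤10 km dated segments by a daily distance budget
(800 km/day at 167 km/h); transect spacing is a free design parameter.
Occupancy: groups arise with intensity
`density_max · expit(β₀ + β₁·z_true + f_depth(depth))` per km², with
`z_true` the driving covariate at the TRUE scale (default 40 km/monthly),
standardised; detection thins them by `g(perpendicular distance)`; group
size is `1 + Poisson(0.5)` (small groups, mostly singletons). Defaults
β₀ = −2, β₁ = 1.5 give a strong covariate effect at a moderate prevalence —
chosen so the scale-recovery question is about *scale discrimination*, not
about detecting whether any effect exists. The cell-level generator
(`simulate_cell_rows`) shortcuts the survey for recovery experiments: one
survey date and a lognormal effort area per cell-year, with observed
presence = occupancy × an effort-dependent encounter probability
`1 − exp(−E/Ē)`, which induces the effort smooth the base model expects.

What the synthetic world does *not* emulate: observer fatigue or
sea-state-dependent detectability, responsive movement, covariance between
different oceanographic variables, non-Gaussian field marginals, coastline
geometry, and spatial autocorrelation of occupancy *beyond* that inherited
from the driving field. Passing recovery tests therefore demonstrates the
statistical machinery, not field performance on real surveys.

## Operating characteristics worth knowing

Two behaviours of the γ = 1.4 UBRE shrinkage procedure, confirmed against
the reference R implementation on identical data, temper expectations:

- A pure-noise smooth is shrunk to EDF < 0.5 in roughly 80% of replicates
  (n = 2,000), not always; occasionally the criterion retains ~0.5–3 EDF of
  spurious structure.
- In the scale-recovery world the base model omits the true driver, so its
  residuals are overdispersed and spatially structured. A *smooth* noise
  field then beats the base model by AIC essentially always (chance
  correlation between smooth fields — the classic spatial-confounding
  problem), and even iid noise columns, best-of-9, undercut the base model
  by >2 AIC in a majority of replicates. Large AIC gains (hundreds of
  units, as the true covariate shows) are trustworthy; gains of a few units
  against a misspecified base are not. The pure-noise null in the
  acceptance experiments uses iid noise slots and reports the measured
  rate.

## Problem sizes

The scale-recovery study uses 50 replicates of a 200 × 200 km world
(2,500 4-km cells × 3 years = 7,500 rows; 61 daily layers per year at 5 km)
with 11 GAM fits per replicate (base + 9 candidates + noise), a few minutes
on one CPU. Unit tests use smaller worlds; the fixture world is the full
default study condition generated once per session.
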