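# Methods

`rangesqueeze` implements a complete analysis of how species' elevation
range sizes relate to temperature variability across and within mountain
gradients: data cleaning and gradient standardization, climate covariate
construction, two Bayesian hierarchical models sampled by blocked Gibbs,
and model comparison and diagnostics. A synthetic-data generator with the
exact statistical structure the models assume makes every stage testable
without any external data.

## The scientific setting

Two opposing hypotheses link temperature variability to range size.
Stevens' hypothesis predicts a *positive* relationship: species in
thermally variable places evolve broad tolerances and therefore occupy
broad ranges. The temperature range squeeze predicts a *negative*
relationship: under a fixed thermal tolerance window `[t_lower, t_upper]`
and a constant lapse rate, a temperature oscillation of amplitude ΔT
shrinks the elevation span in which neither lethal limit is ever crossed:

    span = max(0, t_upper − t_lower − ΔT) / lapse_rate × 100   [m]

(`suitable_habitat_span`; lapse rate in °C per 100 m, default 0.5). The
caption that motivates this calculator does not state the lapse-rate
denominator; 0.5 °C *per 100 m* is adopted — with it, a 20 °C tolerance
window maps to a 4000 m suitable span, which is the physically sensible
scale for real mountains.

## Data model and preprocessing

A dataset is one row per species × mountain with minimum and maximum
recorded elevation (precision ≤ 100 m, handled as floats, never
re-rounded). Range size is `max − min`; a species recorded once is a
*singleton* with range 0 m. Cleaning and standardization run in a fixed
order, enforced by a state guard so stages cannot be run out of order:

1. **Row validation** — drop records with min > max, elevations above
   6500 m (the vascular-plant ceiling), or non-finite values; each
   rejection carries a reason code.
2. **Mountain filters** — drop mountains with > 25 % singletons
   (inclusive at exactly 25 %) or a sampling gap > 500 m. "Sampled
   sections" are the union of the species' elevation intervals (singletons
   contribute points); the union is the only construction available when
   all one has is ranges.  Both filters run on the full pre-standardization
   dataset.
3. **Gradient standardization** — trim every mountain to a common length
   (1500/2000/2500 m), anchored at the top (default) or bottom. Ranges
   crossing the new boundary are truncated to it; ranges entirely outside
   are dropped. Truncation can leave a zero-width range at the boundary;
   these are kept and treated as singletons downstream, consistent with
   the singleton floor. Mountains shorter than the target length are
   excluded and logged (this drives the visible attrition, e.g. 44 → 30
   style, on any dataset).
4. **Exclusion zones** — remove species whose whole range lies within E
   meters of either domain end (E ∈ {0, 250, 500}). Containment is read
   strictly: a range touching the zone's inner edge is kept ("found
   exclusively near" the edge means the whole range is inside the zone).
   E = 0 is the identity.
5. **Transform** — ranges below 10 m are floored at 10 m (the smallest
   observable positive range at 10 m recording precision; this also
   covers sub-10 m truncation leftovers) and natural-log transformed, so
   a singleton contributes ln 10 ≈ 2.303.

## Climate covariates

Band tables hold mean diurnal temperature range (DTR, bio2), temperature
seasonality (TS, bio4), mean annual temperature (MAT, bio1) and annual
precipitation (AP, bio12) in 100 m elevation bands. Bands are half-open
`[lower, upper)` anchored at 0 m — the convention is not dictated by the
problem; half-open intervals avoid double counting. `zonal_band_means`
reduces a DEM/climate grid pair to band means (unweighted pixel means per
band). Mountain-level covariates average the *bands* inside the
(standardized) domain, each band counting once regardless of its pixel
count; a pixel-weighted variant is available behind a flag.

Millennial-scale variability enters as one number per mountain:
ΔMAT₀₋₁₉₈₀, the max − min of a series of 30-year-mean annual temperatures
spanning 0–1980 AD. For the within-mountain analyses, DTR/TS are assigned
at each species' range midpoint (the band whose half-open interval
contains it).

## The two hierarchical models

**Across-mountain (global).** Species log range `y` in mountain `site`:

    y        ~ Normal(alpha_site[site], sigma2_RS)
    alpha_site ~ Normal(X_site · coef, sigma2_site)
    coef     ~ Normal(0, precision 1e-6)
    1/sigma2 ~ Gamma(1e-3, 1e-3)        (both variances)

`X_site` is the mountain-level design: intercept plus one covariate (DTR,
TS or ΔMAT), optionally two covariates plus their product (interaction
models include both main effects — products alone are not identifiable
practice), or island/continental indicator coding with separate
intercepts and slopes. The priors follow the BUGS convention: the second
normal argument is a precision and the gamma prior sits on the precision,
which is the only reading under which they are "flat".

**Within-mountain (local).** Each mountain gets its own intercept and
slope on the midpoint covariate, with a single residual variance shared
by all mountains. ΔMAT is refused as a local covariate: one paleo value
per mountain cannot resolve within-gradient variation. Mountains whose
covariate is constant are flagged and excluded from slope reporting
(their slope posterior is prior-dominated); sampling proceeds for the
rest.

**Sampling.** Both models are sampled by a systematic-scan blocked Gibbs
sampler with closed-form conjugate conditionals: site means (or per-site
intercept/slope pairs) jointly per block, regression coefficients as one
multivariate normal block (drawn in the eigenbasis of XᵀX, precomputed
once), precisions from gamma conditionals. Chains initialize at empirical
site means, least-squares coefficients and method-of-moments precisions.
Defaults: 3 chains × 50,000 iterations, 20,000 burn-in; after the
configured run, chains extend in 10,000-iteration increments (at most 5)
until every parameter's effective sample size reaches 3,000. Everything
is a pure function of (data, config, seed).

Covariates enter on their natural scale: with precision-10⁻⁶ priors the
posterior is invariant to affine rescaling for all practical purposes, so
standardization is a numerical nicety, not a modeling choice.

## Evaluation

* **WAIC** (deviance scale) and **PSIS-LOO** from pointwise
  log-likelihood draws; the Pareto smoothing is arviz's `psislw`,
  observations with tail shape k > 0.7 are flagged. Pointwise
  log-likelihood is stored for a thinned subset of draws (capped near
  7·10⁶ entries per chain, at least 150 draws) to bound memory.
* **P(β < 0)** — fraction of slope draws below zero; equal-tailed 95 %
  credible intervals.
* **Site-level Bayesian R²** — per draw,
  `var(fitted) / (var(fitted) + var(alpha_site − fitted))` over mountains,
  reported as the posterior mean. The original report does not state its
  R² estimator; this draw-wise variance-explained reading is configurable
  and flagged in reports.
* **R̂** — classic split-chain Gelman–Rubin (not rank-normalized),
  matching the JAGS-era toolchain; ≤ 1.01 is the convergence gate.
  All-constant identical chains return exactly 1.
* **ESS** — multi-chain autocorrelation estimator with Geyer's initial
  positive sequence truncation; a constant chain is reported as its total
  draw count with the degeneracy noted at the call site.
* **Posterior predictive checks** — per-site mean/SD/min/max of log range
  under replicated datasets; tail probabilities near 0/1 are flagged.
* **Local slope classification** — sign of the posterior mean, mean/SD
  ratio, and a low-uncertainty flag when the 95 % CI excludes zero, with
  aggregate percentages over mountains.

## The synthetic world

`SyntheticWorldConfig` defaults mirror the study system: 44 mountains, 15
of them islands, spans 1500–6000 m snapped to 100 m, ~2000 species per
mountain, 15 % singletons. Island mountains draw DTR from a lower
distribution (8 ± 1.5 °C) than continental ones (13 ± 2 °C); MAT falls
with elevation at 0.5 °C/100 m; TS and AP are uniform per mountain with
mild band-level jitter. Species log ranges follow the global model
exactly: mountain mean = α_V + β_V·V_site plus Normal(0, σ²_site), species
scatter Normal(0, σ²_RS), back-transformed to meters, placed with a
uniform random midpoint and clipped to the domain (the model itself is
location-free; uniform placement is the simplest choice that exercises
truncation and exclusion logic). A configured fraction of species is
collapsed to singletons (min = max) — reproducing the QC-relevant feature
without modeling sampling effort. Paleo series are Gaussian random walks
rescaled to a requested amplitude (only max − min matters downstream).

What the generator does **not** emulate: spatial autocorrelation of real
climate grids, realistic paleoclimate physics, sampling effort, taxonomy.
Passing tests therefore demonstrate that the *pipeline and inference* are
correct under the model's own assumptions, not that the model is right
for any particular field dataset.

`simulate_global_dataset` draws the global model exactly (no placement or
clipping) for parameter-recovery and calibration experiments where the
model must hold by construction.

## Verification design and problem sizes

* Slope recovery and the convergence gates run at the default MCMC
  settings on 50 replicates of 30 mountains × 100 species (slope −0.1,
  site SD 0.3, species SD 0.8): 95 % CI coverage and absence of
  systematic bias. (Per-replicate |deviation|/posterior-SD is *not* a
  useful bias metric: for a calibrated posterior it averages E|Z| ≈ 0.8.)
* The Gibbs sampler is cross-checked against an independent random-walk
  Metropolis sampler (written separately, in the test suite) on a 3-site
  instance. With 3 sites the between-site variance has one residual
  degree of freedom and the near-scale-invariant gamma prior makes its
  marginal genuinely heavy-tailed — posterior *means* of such marginals
  are not convergent summaries for any sampler, so the comparison uses
  posterior medians (all parameters) plus means of the light-tailed ones.
* PSIS-LOO is checked against brute-force leave-one-out refits on a
  designed n = 20 instance whose residuals are stratified normal scores:
  no extreme observations by construction, so the importance sampling
  stays inside its domain of validity (all Pareto k < 0.7) regardless of
  the MCMC seed.
* Model-comparison fidelity and null-slope calibration run at reduced
  chain lengths (3 × 6,000 and 3 × 2,500) — these experiments need many
  replicates, not long chains, and the chains are short but well past
  mixing for these conjugate models.

## Numerical notes and limitations

* Gamma conditionals are parameterized as shape/rate; draws use
  `Generator.gamma(shape, scale=1/rate)`.
* The ESS extension rule is skipped by setting `target_ess=0` (used in
  replicate experiments).
* Exclusion-zone and truncation edge cases (ranges exactly on a
  boundary) follow closed-interval containment; ties at band boundaries
  go to the upper band.
* With very few sites the variance hyperparameters are prior-dominated
  and heavy-tailed (see above); summaries of `sigma2_site` should be
  medians or quantiles in small-J applications.
* The local model's per-site slopes are unshrunk (no hierarchy across
  slopes), exactly as specified; with weak within-mountain covariate
  variation they are wide, which is itself the substantive finding at
  local scale.
* No GeoTIFF reader is shipped; grids enter as numpy arrays and band
  tables as CSV.
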