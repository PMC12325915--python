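# Methods

This note documents the statistical model, the conversion chain, the
synthetic-data generator and the numerical choices behind `biopyramid`.  It
is written for users who want to know exactly what the package computes and
what the bundled tests do and do not demonstrate.

## Study system and data model

The package targets long-running camera-trap grids of the kind used to
monitor medium and large mammals in the Cantabrian range (northern Spain):
a grid of 5 × 5 km cells with one camera per cell over a 1125 km² study
area, running for several years with irregular interruptions (theft,
vandalism, battery failure).  Raw data are timestamped species records per
station plus a log of the dates each camera was active.

**Independence filtering.** Repeat triggers of the same animal are
collapsed by a greedy rule: within each (station, species) stream sorted by
time, a record is kept iff it is at least 15 minutes (configurable) after
the most recently *kept* record.  The greedy reading is the simplest
consistent interpretation of a minimum-separation rule; it is idempotent
and monotone in the separation threshold, and both properties are tested.

**Occasions.** Kept events are pooled into consecutive 5-day windows
("occasions") anchored at each camera-year's first active day of the
calendar year.  Anchoring is a genuinely open choice (calendar pentads
would be equally defensible); deployment-anchored windows waste no leading
empty occasions and make the first occasion always partially or fully
active.  A trailing partial window is kept — the effort covariate absorbs
its reduced exposure — rather than discarded.  The number of active camera
nights within each occasion (0–5) is carried as an observation-level
covariate; occasions with zero active nights are missing data, not zeros.

**Sample units.** Each camera-year is a separate sample unit.  This trades
the population-closure assumption across years for closure within a year,
at the cost of treating years at one camera as independent; camera identity
is available as an abundance-level fixed effect to soak up persistent
site differences.

## The N-mixture model

For unit *i* and occasion *t*:

    N_i  ~ Poisson(λ_i),         log λ_i = x_i' β
    y_it ~ Binomial(N_i, p_it),  logit p_it = γ₀ + γ₁ · effort_it / 5

The latent N are marginalized by truncated summation to K, giving the
integrated likelihood ∏_i Σ_{N≤K} [∏_t Bin(y_it | N, p_it)] Pois(N | λ_i)
over observed occasions only.

Numerical notes:

* Everything is in log space; per-occasion binomial log-pmfs factor into a
  parameter-free table `A[i, N] = Σ_t log C(N, y_it)` (computed once) plus
  terms linear in N, so one likelihood evaluation is O(units × K) no matter
  how many occasions there are.  The vectorized evaluation is tested to
  1e−10 against a pure-Python triple-loop oracle.
* `log p` and `log(1−p)` are evaluated with log-sigmoids, stable for
  extreme linear predictors.
* Truncation default: K = max observed count + the 1−1e−8 Poisson quantile
  at a naive moment estimate of λ (mean per-unit maximum).  The
  log-likelihood is non-decreasing in K and the default sits where the last
  increment is below 1e−8 (tested).  K below the max count is a hard error.

**Maximum likelihood** (BFGS on the marginal likelihood, standard errors
from the inverse observed information via central-difference Hessian) is
provided as a fast estimator and as an independent cross-check on the
Bayesian fit.  Non-convergence is flagged on the result object, not raised,
because ridge-shaped likelihoods (few occasions, low p) are a legitimate
outcome the caller should see.

**Bayesian fitting** uses independent Normal(0, 10²) priors on all
link-scale coefficients (configurable) — diffuse enough to be
likelihood-dominated at survey data volumes — and an adaptive random-walk
Metropolis sampler on the marginalized posterior.  The default protocol is
4 chains × 4000 sweeps, first 2000 discarded, no thinning: 8000 retained
draws.  During burn-in a global proposal scale chases 30% acceptance
(Robbins–Monro) and the proposal covariance tracks the running empirical
covariance (Haario-style, scaled 2.38²/d); adaptation freezes at the end of
burn-in so the retained chain is a valid Markov chain.  Draws are
bit-reproducible given (seed, data, settings); chains use independent
`SeedSequence` spawns.  The sampler is deliberately simple: with the
marginal (low-dimensional) parameterization, random-walk Metropolis mixes
well for intercept + effort models.  For models with many camera fixed
effects it will mix slowly; that is a known limitation, and the MLE is the
practical alternative there.

**Convergence** is assessed by the classical (non-split) Gelman–Rubin
potential scale reduction factor √(((n−1)/n · W + B/n)/W), flagged above
1.1.  Identical chains give √((n−1)/n) < 1, which is reported with a note
rather than clipped.  Zero within-chain variance yields an undefined (NaN)
value, flagged.  Rank-normalized split-R̂ variants give different numbers
by construction; the classical statistic is the documented contract here.

**Relative abundance** — the average number of animals per camera station
— is computed per retained draw as the across-unit mean of λ_i and then
summarized (posterior mean, central 95% interval).  Averaging per-unit
posterior means instead yields the identical point estimate by linearity;
only the interval distinguishes the two readings, and the unit-averaged-λ
posterior is the one reported.

## From abundance to biomass

Per species, with traits (adult body mass, mean group size, median home
range in similar environments):

    density [ind km⁻²]  = relative abundance × group size / home range [km²]
    total abundance     = density × study area (default 1125 km²)
    biomass [t]         = total abundance × body mass [kg] / 1000

The species' median home range is used as the effective capture area of
every camera — a deliberate, crude approximation (no detection-distance
geometry) that makes densities extremely sensitive to the home-range value
used; this is the dominant systematic uncertainty of the whole chain.

The pyramid summary pools biomass by trophic group (primary consumers,
secondary consumers, omnivores) and by taxonomic order; the trophic
transfer rate is 100 × secondary/primary and the prey:predator ratio its
reciprocal ×100, so transfer × ratio = 100 exactly before any rounding.
Pooled values are always sums of member species.  All arithmetic is kept at
full precision; half-up rounding to display precision lives only in the
report layer, because published tables mix rounded, truncated and
unrounded intermediates (the bundled reference table's kg km⁻² and
percentage columns are internally inconsistent at the last printed digit,
and the tests allow exactly one printed ulp for those columns).

## Plant biomass and the available fraction

Grid-cell above-ground biomass (AGB, tonnes per cell) and annual NPP
(tonnes per cell per year) enter as a table — the remote-sensing modelling
that produces them is out of scope.  Per cell, annual NPP is averaged over
years and divided by the cell's AGB; the unweighted mean of these per-cell
fractions (each cell counts equally, following the aggregation as
described; an AGB-weighted mean is available behind a flag) times the
study-area AGB total gives the biomass considered available to herbivores.
Cells with zero AGB are excluded from the fraction average (undefined
ratio) but kept in totals.  Densities are totals over the study area,
full-precision; the report layer prints integers.

## Synthetic surveys

The generator emulates the survey design so every pipeline stage is
testable without the original data:

* Activity: each camera-day is active with probability
  `activity_fraction` (default 0.85), runs merged into intervals — an
  irregular activity pattern with single-day gaps, harsher than real
  outage patterns (which cluster), which is the conservative direction for
  testing effort accounting.  An optional deployment window
  (`days_per_year`) shortens the season.
* Abundance: N per camera-year ~ Poisson(exp(β₀ + c_s)), camera effects
  c_s ~ Normal(0, sd) fixed per station across years — exactly the
  fixed-effect structure the estimator can represent.
* Detection: per-occasion Binomial(N, p_it) with logit p_it = γ₀ + γ₁ ·
  effort/5.
* Events: detected counts are exploded into timestamps on active days,
  round-robin across the occasion's active days, 20 minutes apart within a
  day, so the 15-minute filter is a no-op and the detections module
  reconstructs the simulated count matrix *exactly* (tested on 20 random
  configurations).  A burst mode injects sub-15-minute repeats to exercise
  the filter.
* Plant cells: lognormal AGB; a latent NPP:AGB fraction per cell,
  Normal(mean 0.125, sd 0.02 by default) truncated to (0, 1); annual NPP =
  AGB × fraction × multiplicative year noise (cv 0.05).  The recorded truth
  is the across-cell mean latent fraction — the estimand of the
  aggregation module.

What the generator does **not** emulate: animal movement and home-range
geometry (the capture-area approximation is assumed, not simulated), bait
attraction, clustered outages, misidentification, and between-year
abundance trends.  Passing recovery tests therefore demonstrate that the
estimation chain inverts its own generative assumptions at survey-like
sample sizes — not that those assumptions hold in the field.

## Test problem sizes

Deterministic correctness checks run on tiny instances against brute-force
enumeration, grid-search and 2-D quadrature oracles.  Stochastic checks
use: 20 replicate surveys of 200 units × 6 occasions (λ = 2, p = 0.4) for
estimator bias (<10%) and interval coverage (≥17/20); and one full-pipeline
run at the survey's shape — 45 cameras × 5 years, ~73 occasions/year —
requiring species biomass recovery within 15% for common species (λ ≥
0.5).  Rarer species carry proportionally more Monte Carlo noise from the
realized latent abundances themselves (sd ≈ √(λ/units)/λ), which is why
the recovery bound applies to common species.

## Known limitations

* Random-walk Metropolis mixes poorly with many camera fixed effects; use
  the MLE or longer chains there.
* Counts are independent events per occasion, not distinct individuals;
  with high re-trigger rates the binomial observation model is optimistic.
  The truncation bound handles the resulting heavy counts but cannot fix
  the model misspecification.
* No uncertainty propagation from posterior abundance draws through the
  biomass chain into pyramid intervals; the summary reports point values
  (the per-species posterior intervals are available upstream).
* The bundled trait table is a synthetic, internally consistent stand-in,
  not measured field data; see `biopyramid.datasets`.
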