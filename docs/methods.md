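# Methods

## Scope and design

`vgm` implements a complete analysis pipeline for testing whether the
vagrancy of migratory landbirds covaries with geomagnetic disturbance and
solar activity. All stages are library code under `src/vgm`; the numbered
scripts under `analysis/` are thin drivers. Because the real inputs (a
continental banding archive, weekly relative-abundance rasters, observatory
index downloads, published phylogenies) are out of reach for a desk-scale
package, a first-class synthetic-data module generates all five input kinds
from a single seed with known generative parameters, and the statistical
claims of the package are validated as *recovery* and *calibration*
properties on those synthetic worlds.

## Vagrancy index

For each species-week, `n = 10,000` points are drawn from the weekly
abundance surface: cells multinomially with probability proportional to
abundance over unmasked cells, then a uniform jitter inside the cell. The
index for a record is the mean haversine distance (Earth radius fixed at
6371 km) to the `k = 10` nearest points. Conventions, chosen where any
reasonable analyst would have to choose:

- One point cloud per species-week, shared by every record of that
  species-week and keyed deterministically on `(seed, species, week)` — the
  index depends only on a record's location, never on record order or on
  which other species are present.
- Week of year is `(day_of_year − 1) // 7 + 1`, capped at 52.
- Records on masked or off-grid cells are flagged `excluded_out_of_range`
  and dropped from modeling.
- Exact zeros (a record sitting on ≥ k sampled points) are floored to half
  the smallest positive index of that species, because the gamma likelihood
  excludes zero.
- Uniform within-cell jitter is uniform in lon/lat, not equal-area; at the
  cell sizes used here (≤ 1°, mid-latitudes) the distortion is well below
  the index's sampling noise. This is a stated approximation.

## Covariates

The rolling covariate at day *t* is the mean of the raw daily index over
days *t−20..t* (trailing, inclusive of the record day; the window length
reflects the latency between a disturbance event and the capture of an
affected bird). The first 20 days of a series are undefined and joining a
record onto them is a hard error — no interpolation anywhere.
Standardization is z-scoring with the *population* SD, computed over record
dates for indices and over the species set for traits; the fitted transform
(mean, SD) is retained so "+2 SD" statements can be mapped back to raw index
units. Seasonal centroids are arithmetic means of abundance-weighted point
samples pooled over a season's weeks (dateline-crossing ranges are rejected
rather than mishandled), and migration length is the haversine distance
between the breeding and nonbreeding centroids.

## Record preparation

Inclusion rules, applied row-wise with per-rule exclusion counts: banding
code 3 (ordinary wild-bird captures); record types banding and encounter
(recaptures dropped as inconsistently reported); location precision ≤ 10 km
(exactly 10 km is retained); capture date inside the species' seasonal
migration window (inclusive endpoints) and outside every taxonomic
exclusion window; optionally, known age only (the spring-style analysis).
Species with fewer than 100 season records are dropped (exactly 100 is
retained).

Thinning caps each species at 20,000 records with per-record inclusion
probability inversely proportional to its species-year record count, so
low-density years keep representation. This is a fixed-size
probability-proportional-to-size design, realized by systematic sampling on
a random permutation with iterative capping of probabilities at 1. A
sequential-weighted-draw scheme was considered and rejected: its inclusion
probabilities are 1 − exp(−wτ), not proportional to w, and it demonstrably
over-samples high-count years (with two years of equal total weight it
yields a 61/39 split where the inverse-density law requires 50/50).

## Hierarchical gamma models

Observation model: `y_j ~ Gamma(shp_i, shp_i / exp(lp_j))`, so
`E[y_j] = exp(lp_j)` and the shape parameter is species-specific (index
distributions differ across species by construction and are only comparable
within species).

Single-driver form: `lp_j = α_{t,i} + β_{t,i} X_j + λ_i age_j + ν_i age_j X_j`
with hierarchy `α_{t,i} ~ N(γ_i, σ_α)`, `γ_i ~ N(μ_γ, σ_γ)`,
`β_{t,i} ~ N(μ_{βi}, σ_β)`, `μ_{βi} ~ N(δ_i, σ_δ)`,
`δ_i = ω + ψ·ml_i + η·bl_i`, `λ_i ~ N(μ_λ, σ_λ)`, `ν_i ~ N(μ_ν, σ_ν)`,
`shp_i ~ N(μ_shp, σ_shp)` truncated to (0, ∞) with the truncation constant
carried in the hyperparameter updates. Interaction form:
`lp_j = α_{t,i} + β_i X1_j + θ_i X2_j + ω_i X1_j X2_j` with species-level
slopes (`β_i`, not `β_{t,i}`: with two drivers and an interaction,
year-by-species slopes in both drivers would be weakly identified at desk
scale) and a two-level intercept hierarchy `α_{t,i} → μ_{αi} → γ`. The
interaction form always drops the age terms.

**Priors** (weakly informative on the standardized scale, configurable in
`vgm.sampler`): N(0, 1) for every effect-scale top-level mean (ω, ψ, η,
μ_λ, μ_ν, μ_β, μ_θ, μ_ω); N(0, 5) for intercept-level means (μ_γ, γ),
which live on the log-km scale (≈ 4 for a 55 km typical index) and would be
visibly biased by a unit-scale prior; half-N(0, 1) for every σ;
half-N(0, 5) for μ_shp with half-N(0, 1) for σ_shp; Beta(2, 2) for the age
prevalences π_i.

**Age imputation.** Unknown ages are sampled as discrete latent Bernoulli
variables inside the Gibbs sweep (posterior `P(age=1) ∝ π_i·L(y|age=1)`),
with π_i conjugately updated from known plus imputed ages. With a
Gibbs-style sampler this targets exactly the same posterior as analytic
marginalization of the two-component mixture and keeps every row in the
likelihood regardless of age information.

**Sampler.** No gradient-based PPL is part of the package's dependency
footprint; the models are fit with a purpose-built seeded adaptive
Metropolis-within-Gibbs sampler:

- conjugate Gibbs draws for all normal-hierarchy means and for the trait
  regression (ω, ψ, η) as a conjugate multivariate normal;
- vectorized parallel single-site Metropolis for the blocks entering the
  gamma likelihood (α cells, β cells, λ_i, ν_i, shp_i) — valid because the
  likelihood factorizes over disjoint row groups;
- log-scale random walks for all σ and for the shape hyperparameters;
- joint *ridge moves* that shift a species' intercepts and its age offset
  (or its slopes and its age-slope) in opposite directions, traversing the
  near-collinear directions that single-site updates crawl along when most
  records are hatch-year;
- *global translation moves* that shift an entire level and its mean
  together (per trait-regression column, and for μ_λ, μ_ν), so top-level
  means decouple from slow child mixing.

Proposal scales adapt per component during warmup only (Robbins–Monro
toward 35% acceptance) and are frozen for the sampling phase. Convergence
is screened on the top-level parameters with split R-hat ≤ 1.05 and bulk
ESS ≥ 100 (arviz); `fit` raises by default when the screen fails. Defaults
are 4 chains × 1000 warmup + 1000 draws; the test suite and acceptance
script use 2 chains with sizes stated inline.

**Summaries.** Posterior medians with equal-tailed 95% credible intervals;
the tail probability is the share of draws above zero when the median is
positive, below zero otherwise. `predicted_change_percent(effect, Δ)` is
the log-link transform `100·(exp(effect·Δ) − 1)`.

**Bayesian R².** Per draw and species, `g_j = β_i X1_j + θ_i X2_j +
ω_i X1 X2` and `ε_j = y_j − g_j`; R² = V(g)/(V(g)+V(ε)), reported as the
species posterior medians and their cross-species median. Note the residual
subtracts a log-link quantity from the raw response: the decomposition is
dimensionally coherent only when `exp(intercept) ≈ 1`, and degenerates to
R² ≈ 0 when the response scale dwarfs the covariate contribution. The
calibration experiment therefore generates data with intercepts at zero and
the gamma shape chosen so residual variance is three times the
covariate-signal variance, where the statistic must land near 0.25. This
scale sensitivity is a known limitation of the definition as stated.

**Posterior predictive checks.** Replicated datasets are drawn from the
fitted gamma likelihood per (thinned) posterior draw; per-species tail
probabilities of mean, SD, max or the share above the observed 90th
percentile. On data generated from the model itself these are roughly
uniform; extreme values flag misfit.

## Synthetic worlds

`gen_world` emulates the five real input kinds:

- **Abundance surfaces**: one truncated-Gaussian bump per species-week
  (bandwidth 3°, mask at 3 bandwidths) whose centroid interpolates between
  a breeding and a nonbreeding center across the migration windows (spring
  weeks 14–22, fall weeks 33–44), normalized to unit mass over the mask.
- **Index series**: daily AR(1) noise (coefficient 0.7) around sinusoidal
  baselines — a 27-day cycle with mean ≈ 12.9 for the geomagnetic series, a
  ~11-year cycle with mean ≈ 56.8 for the solar series — floored at zero
  (both physical indices are nonnegative). The series start a year before
  the first study year so every record date has a defined 21-day mean. The
  two series are generated independently, so the pipeline's reported
  Pearson correlation between them is near zero on synthetic data (on real
  indices it is substantially positive); nothing downstream depends on it.
- **Records**: `model_level` mode draws vagrancy values directly from the
  gamma observation model with a full hierarchical parameter draw
  (generative twins of every model parameter), which is what all
  recovery/calibration claims use. `spatial` mode places records on the map
  by displacing a surface draw by an exponential distance with scale
  `exp(lp)` in a uniform direction — a stand-in law (nothing in the problem
  dictates a displacement mechanism) whose only purpose is to exercise the
  geometric pipeline end-to-end with a monotone link to the linear
  predictor. The per-record signal in spatial mode is heavily diluted by
  the displacement noise, so end-to-end spatial fits at desk scale have
  little power; this is expected and is why recovery tests use model-level
  data.
- **Traits and phylogenies**: diurnal fraction ≈ 24%; Yule trees (dendropy
  birth-death with zero death rate, tip edges extended by the censored next
  speciation time so the phylogenetic covariance matrix is full-rank), with
  tip values evolved by Brownian motion or drawn i.i.d. for the
  signal-free regime.

Default effect sizes are the study conditions the package emulates:
ω = 0.109 per SD, μ_λ = 0.054, ψ = 0.039, η = −0.004, μ_ν = 0.006 for the
single-driver world; μ_β = 0.079, μ_θ = −0.020, μ_ω = −0.025 for the
interaction world; 30% of ages masked to unknown.

What passing tests do and do not show: synthetic worlds have clean
Gaussian ranges, no observer-effort gradients, no taxonomic ambiguity
beyond the configurable exclusion windows, and gamma-distributed vagrancy
by construction. Recovery and calibration results therefore validate the
*inference machinery* (likelihood, hierarchy, imputation, sampler,
summaries), not the adequacy of the gamma model or of the index for real
banding data — on real data those questions are what the posterior
predictive checks and the index diagnostics are for.

## Post-hoc tests

Blomberg's K is computed from the phylogenetic variance–covariance matrix:
K = (MSE0/MSE) / E_BM[MSE0/MSE] with the phylogenetically corrected mean,
GLS mean squared error, and the Brownian expectation
`(tr V − n/1'V⁻¹1)/(n−1)`. It is affine-invariant and is cross-checked in
the test suite against the independent R implementation (`picante::Kcalc`).
Scoring over a tree set reports the per-tree K with median and range. The
diel comparison uses Welch's unequal-variance t-test (robust default; the
pooled test is recoverable by equal group variances), excluding species
labelled `both` or `unknown`.

## Problem sizes and determinism

Desk-scale sizes were chosen so the full suite and the acceptance script
each run in minutes on one CPU: recovery uses 20 replicates of 15 species ×
8 years × 20 records/year (coverage of a correctly computed 95% CrI is
sample-size invariant — smaller data only widens intervals), null
calibration 40 replicates of 10 × 6 × 15, and the acceptance script's
headline fits 20 × 8 × 40 (single-driver) and 15 × 8 × 30 (interaction).
Every random stage (world, records, clouds, chains, trees) is driven by an
explicit seed; identical seeds give bitwise-identical outputs.

## Known limitations

- The spatial displacement law is a stand-in; spatial-mode fits are
  exercised, not power-tested.
- The Bayesian R² definition mixes response and log-link scales (above);
  it is reported as defined, with the calibration experiment confined to
  the regime where it is coherent.
- Uniform in-cell jitter is not equal-area; negligible at ≤ 1° cells.
- The week convention (day-of-year // 7, capped) differs from ISO weeks by
  at most one week near year end.
- The Metropolis-within-Gibbs sampler mixes more slowly than a tuned HMC
  implementation would on the same model; the ridge and translation moves
  recover most of the gap at these sizes, and the R-hat/ESS screen guards
  the rest.
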