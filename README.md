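# vgm — geomagnetic disturbance, solar activity, and avian vagrancy

`vgm` is a desk-scale, fully testable implementation of an analysis pipeline
linking the vagrancy of migratory landbirds to geomagnetic disturbance (an
Ap-like index) and solar activity (a sunspot-number proxy). It is written for
movement ecologists and biostatisticians who want to exercise, validate, or
extend every stage of such an analysis without access to the original
multi-million-record banding dataset: a synthetic-world generator with known
ground truth stands in for the real inputs, and every downstream stage —
filtering, index construction, covariates, hierarchical Bayesian models,
post-hoc tests — is ordinary, importable library code.

## The analysis

**Vagrancy index.** A banding record's spatiotemporal rarity is measured
against the species' expected range for that week: 10,000 points are
simulated from the weekly relative-abundance surface (cells drawn
proportionally to abundance, jittered within cells), and the record's
vagrancy index is the mean great-circle distance (km) to its 10 nearest
points. Records outside the modeled range are excluded. Index values are
comparable only within species; the models below absorb this with
species-specific gamma distributions.

**Covariates.** Each record is matched by date to the trailing 21-day mean
of the daily geomagnetic and solar indices. Indices and species traits
(migration length and breeding latitude, derived from abundance-weighted
seasonal centroids) are z-standardized.

**Hierarchical gamma models.** Vagrancy y_j for record j (species i, year t)
is modeled on a log link,

    y_j ~ Gamma(shp_i, shp_i / exp(lp_j))            E[y_j] = exp(lp_j)

with the single-driver form

    lp_j = α_{t,i} + β_{t,i}·X_j + λ_i·age_j + ν_i·age_j·X_j

where X is the standardized rolling driver and age is 1 for hatch-year
birds. Parameters are hierarchical: α_{t,i} ~ N(γ_i, σ_α), β_{t,i} ~
N(μ_{βi}, σ_β), and the species sensitivity mean is regressed on traits,

    μ_{βi} ~ N(δ_i, σ_δ),   δ_i = ω + ψ·migration_length_i + η·breeding_latitude_i

so ω is the cross-species driver effect per SD. Unknown ages (a large
fraction of real banding data) are imputed inside the model via a latent
Bernoulli with species prevalence π_i. The two-driver interaction form drops
the age terms and fits lp_j = α_{t,i} + β_i·X1_j + θ_i·X2_j + ω_i·X1_j·X2_j
with every slope hierarchical; per-species variance explained (Bayesian R²)
is V(g)/(V(g)+V(ε)) for the covariate contribution g.

Posterior sampling uses the package's adaptive Metropolis-within-Gibbs
sampler (conjugate updates for the normal hierarchy, vectorized
Metropolis for the gamma-likelihood blocks, joint ridge/translation moves
for the age-intercept and effect-mean directions); convergence is screened
with split R-hat and effective sample size.

**Post-hoc tests.** Phylogenetic signal in fitted species sensitivities is
scored by Blomberg's K over a set of candidate trees (K ≈ 1 under Brownian
evolution, ≪ 1 for no signal; cross-checked against R's `picante`), and
nocturnal vs. diurnal migrants are compared with a Welch t-test.

## Worked example

```python
from vgm import (ModelSpec, TruthParams, WorldConfig, build_inputs, fit,
                 gen_banding_records, gen_world, predicted_change_percent,
                 summarize)

world = gen_world(WorldConfig(n_species=15, n_years=8, seed=1))
records, truth = gen_banding_records(world, TruthParams(), n_per_species_year=30, seed=2)
spec = ModelSpec(chains=2, warmup=1000, draws=2000, seed=3)
result = fit(spec, build_inputs(records, spec))

omega = summarize(result, "omega")
print(f"omega: {omega['median']:.3f} (95% CrI {omega['cri_low']:.3f} to {omega['cri_high']:.3f}), "
      f"{omega['tail_side']} = {omega['tail_prob']:.2f}")
print(f"+2 SD geomagnetic shift: {predicted_change_percent(omega['median'], 2):.1f}% "
      f"change in predicted vagrancy (generative value {truth['params']['omega_true']})")
```

prints

```
omega: 0.105 (95% CrI 0.050 to 0.156), p(>0) = 1.00
+2 SD geomagnetic shift: 23.3% change in predicted vagrancy (generative value 0.109)
```

i.e. the cross-species geomagnetic effect is recovered (the 95% credible
interval covers the generative 0.109 per SD), and on the log link a
two-standard-deviation increase in 21-day geomagnetic disturbance predicts
a ~23% increase in the typical species' vagrancy index.

## The analysis, step by step

The numbered scripts under `analysis/` run the pipeline as a narrative:

1. `01_simulate_world.py` — synthetic world + map-level fall records
2. `02_prepare_records.py` — inclusion filters, season minimum, thinning
3. `03_vagrancy_index.py` — point clouds and the k-nearest index
4. `04_covariates.py` — 21-day rolling joins, standardization
5. `05_fit_models.py` — single-driver and interaction model fits
6. `06_posthoc.py` — Blomberg's K and the diel comparison

Each writes its tables to `results/` (intermediates to `scratch/`).

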