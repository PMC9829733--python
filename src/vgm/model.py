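"""Hierarchical Bayesian gamma models of vagrancy.

Two model forms are fit, both with the observation model
``y_j ~ Gamma(shp_i, shp_i / exp(lp_j))`` so that ``E[y_j] = exp(lp_j)``:

* ``single_driver`` — lp_j = alpha_{t,i} + beta_{t,i} X_j + lambda_i age_j
  + nu_i age_j X_j, with species-specific parameters drawn from group-level
  normals and the species sensitivity mean regressed on standardized traits
  (delta_i = omega + psi migration_length_i + eta breeding_latitude_i).
  Unknown ages are imputed (latent Bernoulli with species prevalence pi_i).
* ``interaction`` — lp_j = alpha_{t,i} + beta_i X1_j + theta_i X2_j
  + omega_i X1_j X2_j (age terms removed), every slope hierarchical.

Posterior draws come from the in-package Metropolis-within-Gibbs sampler;
convergence is screened with split R-hat and effective sample size (arviz).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .sampler import InteractionSampler, SingleDriverSampler, run_chain

TOP_LEVEL_SINGLE = ["omega", "psi", "eta", "mu_lambda", "mu_nu", "mu_gamma", "mu_shp"]
TOP_LEVEL_INTERACTION = ["mu_beta", "mu_theta", "mu_omega", "gamma", "mu_shp"]


@dataclass
class ModelSpec:
    form: str = "single_driver"          # or "interaction"
    season: str = "fall"
    driver: str = "geomagnetic"          # single_driver: which index is X
    include_age_terms: bool = True
    trait_regression: bool = True
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    ess_threshold: float = 100.0

    def __post_init__(self):
        if self.form not in {"single_driver", "interaction"}:
            raise ValueError("form must be 'single_driver' or 'interaction'")
        if self.form == "interaction" and self.include_age_terms:
            # age terms are removed from the interaction model for tractability
            self.include_age_terms = False
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")


@dataclass
class ModelInputs:
    y: np.ndarray
    s_idx: np.ndarray
    t_idx: np.ndarray
    species: list[str]
    years: list[int]
    X: np.ndarray | None = None
    X1: np.ndarray | None = None
    X2: np.ndarray | None = None
    age: np.ndarray | None = None        # 0 adult, 1 young, -1 unknown
    trait_design: np.ndarray | None = None  # (S, P), column 0 = ones

    @property
    def n(self) -> int:
        return len(self.y)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PosteriorDraws:
    """Posterior draws keyed by parameter, shaped (chains, draws[, dim])."""

    draws: dict[str, np.ndarray]
    species: list[str]
    diagnostics: pd.DataFrame
    converged: bool
    inputs: ModelInputs | None = None
    spec: ModelSpec | None = None

    def pooled(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(
                f"unknown parameter {name!r}; available: {sorted(self.draws)}"
            )
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        rows = []
        for name, arr in self.draws.items():
            chains, ndraws = arr.shape[:2]
            if arr.ndim == 2:
                for c in range(chains):
                    rows.append(pd.DataFrame({
                        "chain": c, "iteration": np.arange(ndraws),
                        "parameter": name, "value": arr[c]}))
            else:
                for d in range(arr.shape[2]):
                    label = f"{name}[{self.species[d]}]" if arr.shape[2] == len(self.species) else f"{name}[{d}]"
                    for c in range(chains):
                        rows.append(pd.DataFrame({
                            "chain": c, "iteration": np.arange(ndraws),
                            "parameter": label, "value": arr[c, :, d]}))
        return pd.concat(rows, ignore_index=True)


def build_inputs(table: pd.DataFrame, spec: ModelSpec) -> ModelInputs:
    """Assemble dense model arrays from a vagrancy table with covariates.

    Rows flagged ``excluded_out_of_range`` are dropped. Unknown-age rows are
    kept (the sampler imputes them); a known-age-only analysis (spring style)
    should pre-filter with ``FilterConfig(require_known_age=True)``.
    """
    df = table.copy()
    if "excluded_out_of_range" in df.columns:
        df = df[~df["excluded_out_of_range"].astype(bool)]
    if (df["vagrancy_km"] <= 0).any():
        raise ValueError(
            "vagrancy values must be positive for the gamma likelihood; "
            "apply the zero-flooring step in compute_vagrancy_table first"
        )
    species = sorted(df["species_code"].unique())
    years = sorted(pd.to_datetime(df["date"]).dt.year.unique())
    if len(species) < 2 or len(years) < 2:
        raise ValueError("need at least 2 species and 2 years")
    s_map = {c: i for i, c in enumerate(species)}
    y_map = {v: i for i, v in enumerate(years)}
    s_idx = df["species_code"].map(s_map).to_numpy()
    t_idx = pd.to_datetime(df["date"]).dt.year.map(y_map).to_numpy()

    age = None
    if "age_class" in df.columns:
        age = df["age_class"].map({"adult": 0, "young": 1, "unknown": -1}).to_numpy()

    trait_design = None
    if spec.trait_regression and "migration_length_z" in df.columns:
        per_species = (
            df.groupby("species_code")[["migration_length_z", "breeding_latitude_z"]]
            .first()
            .loc[species]
        )
        trait_design = np.column_stack(
            [np.ones(len(species)), per_species.to_numpy()]
        )
    elif spec.trait_regression:
        trait_design = np.ones((len(species), 1))

    kwargs = dict(
        y=df["vagrancy_km"].to_numpy(float),
        s_idx=s_idx,
        t_idx=t_idx,
        species=species,
        years=[int(v) for v in years],
        age=age,
        trait_design=trait_design,
    )
    if spec.form == "single_driver":
        col = "geomag_z" if spec.driver == "geomagnetic" else "solar_z"
        kwargs["X"] = df[col].to_numpy(float)
    else:
        kwargs["X1"] = df["geomag_z"].to_numpy(float)
        kwargs["X2"] = df["solar_z"].to_numpy(float)
    return ModelInputs(**kwargs)


def fit(spec: ModelSpec, inputs: ModelInputs, check_convergence: bool = True) -> PosteriorDraws:
    """Fit the requested model; raises ConvergenceError when diagnostics fail
    (pass ``check_convergence=False`` to get the flagged draws instead)."""
    chains = []
    for c in range(spec.chains):
        rng = np.random.default_rng([int(spec.seed), c])
        if spec.form == "single_driver":
            age = inputs.age if inputs.age is not None else np.zeros(inputs.n, int)
            design = inputs.trait_design if inputs.trait_design is not None else np.ones(
                (len(inputs.species), 1))
            sampler = SingleDriverSampler(
                inputs.y, inputs.X, inputs.s_idx, inputs.t_idx, age, design, rng,
                include_age_terms=spec.include_age_terms,
            )
        else:
            sampler = InteractionSampler(
                inputs.y, inputs.X1, inputs.X2, inputs.s_idx, inputs.t_idx, rng)
        chains.append(run_chain(sampler, spec.warmup, spec.draws, spec.thin))

    draws = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    top = TOP_LEVEL_SINGLE if spec.form == "single_driver" else TOP_LEVEL_INTERACTION
    top = [p for p in top if p in draws]
    ds = az.convert_to_dataset({p: draws[p] for p in top})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    diag = pd.DataFrame(
        {
            "parameter": top,
            "rhat": [float(rhat[p]) for p in top],
            "ess": [float(ess[p]) for p in top],
        }
    )
    converged = bool(
        (diag["rhat"] <= spec.rhat_threshold).all()
        and (diag["ess"] >= spec.ess_threshold).all()
    )
    result = PosteriorDraws(
        draws=draws, species=inputs.species, diagnostics=diag,
        converged=converged, inputs=inputs, spec=spec,
    )
    if check_convergence and not converged:
        bad = diag[(diag["rhat"] > spec.rhat_threshold) | (diag["ess"] < spec.ess_threshold)]
        raise ConvergenceError(
            f"chains not converged:\n{bad.to_string(index=False)}"
        )
    return result


def summarize(result: PosteriorDraws, name: str, index: int | None = None) -> dict:
    """Posterior median, equal-tailed 95% CrI and tail probability.

    The tail probability follows the reporting convention for effect tables:
    share of draws > 0 when the median is positive, otherwise share < 0.
    """
    pooled = result.pooled(name)
    if pooled.ndim == 2:
        if index is None:
            raise ValueError(f"{name} is vector-valued; pass index=")
        pooled = pooled[:, index]
    median = float(np.median(pooled))
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    if median > 0:
        tail = float(np.mean(pooled > 0))
        tail_side = "p(>0)"
    else:
        tail = float(np.mean(pooled < 0))
        tail_side = "p(<0)"
    return {
        "median": median,
        "cri_low": float(lo),
        "cri_high": float(hi),
        "tail_prob": tail,
        "tail_side": tail_side,
    }


def predicted_change_percent(effect_per_sd: float, delta_sd: float) -> float:
    """Percent change in predicted vagrancy for a covariate shift of
    ``delta_sd`` standard deviations, under the log link:
    100 * (exp(effect * delta) - 1)."""
    return 100.0 * (np.exp(effect_per_sd * delta_sd) - 1.0)


def bayesian_r2(result: PosteriorDraws, inputs: ModelInputs | None = None,
                max_draws: int = 400) -> dict:
    """Per-species posterior-median variance explained by the covariates.

    For each draw and species: g_rep_j = beta_i X1_j + theta_i X2_j
    + omega_i X1_j X2_j, residual e_j = y_j - g_rep_j, and
    R2 = V(g_rep) / (V(g_rep) + V(e)). Reports species posterior medians and
    their cross-species median. Requires interaction-model draws.
    """
    inputs = inputs if inputs is not None else result.inputs
    for p in ("beta_i", "theta_i", "omega_i"):
        if p not in result.draws:
            raise ValueError("bayesian_r2 requires interaction-model draws")
    b = result.pooled("beta_i")
    th = result.pooled("theta_i")
    om = result.pooled("omega_i")
    total = b.shape[0]
    step = max(1, total // max_draws)
    idx = np.arange(0, total, step)

    S = len(inputs.species)
    s = inputs.s_idx
    counts = np.bincount(s, minlength=S).astype(float)
    r2 = np.full((len(idx), S), np.nan)
    for out_row, d in enumerate(idx):
        g = b[d, s] * inputs.X1 + th[d, s] * inputs.X2 + om[d, s] * inputs.X1 * inputs.X2
        e = inputs.y - g
        gm = np.bincount(s, g, minlength=S) / counts
        em = np.bincount(s, e, minlength=S) / counts
        vg = np.bincount(s, (g - gm[s]) ** 2, minlength=S) / counts
        ve = np.bincount(s, (e - em[s]) ** 2, minlength=S) / counts
        denom = vg + ve
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[out_row] = np.where(denom > 0, vg / denom, np.nan)
    per_species = np.nanmedian(r2, axis=0)
    return {
        "per_species": dict(zip(inputs.species, per_species.astype(float))),
        "cross_species_median": float(np.nanmedian(per_species)),
    }


def posterior_predictive_check(
    result: PosteriorDraws, inputs: ModelInputs | None = None,
    statistic: str = "mean", max_draws: int = 200, seed: int = 0,
) -> pd.DataFrame:
    """Per-species PPC tail probabilities: share of replicated statistics
    exceeding the observed one under the fitted gamma likelihood."""
    inputs = inputs if inputs is not None else result.inputs
    stats_fns = {
        "mean": np.mean,
        "sd": lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0,
        "max": np.max,
        "prop_above_q90": None,  # handled below, needs the observed q90
    }
    if statistic not in stats_fns:
        raise ValueError(f"statistic must be one of {sorted(stats_fns)}")

    s = inputs.s_idx
    S = len(inputs.species)
    q90 = {i: np.quantile(inputs.y[s == i], 0.9) for i in range(S)}

    def species_stat(values, i):
        if statistic == "prop_above_q90":
            return float(np.mean(values > q90[i]))
        return float(stats_fns[statistic](values))

    observed = np.array([species_stat(inputs.y[s == i], i) for i in range(S)])

    lp_draws = _lp_draws(result, inputs, max_draws)
    shp = result.pooled("shp_i")
    step = max(1, shp.shape[0] // lp_draws.shape[0])
    shp = shp[::step][: lp_draws.shape[0]]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(S)
    for d in range(lp_draws.shape[0]):
        shp_row = shp[d, s]
        y_rep = rng.gamma(shape=shp_row, scale=np.exp(lp_draws[d]) / shp_row)
        for i in range(S):
            if species_stat(y_rep[s == i], i) > observed[i]:
                exceed[i] += 1
    return pd.DataFrame(
        {
            "species_code": inputs.species,
            "statistic": statistic,
            "tail_prob": exceed / lp_draws.shape[0],
        }
    )


def _lp_draws(result: PosteriorDraws, inputs: ModelInputs, max_draws: int) -> np.ndarray:
    """Row linear predictors for a thinned set of pooled posterior draws."""
    alpha = result.pooled("alpha_cell")
    total = alpha.shape[0]
    step = max(1, total // max_draws)
    sel = np.arange(0, total, step)
    S = len(inputs.species)
    raw = inputs.t_idx * S + inputs.s_idx
    cell_codes = np.unique(raw)
    cell = np.searchsorted(cell_codes, raw)

    if "beta_cell" in result.draws:  # single-driver form
        beta = result.pooled("beta_cell")[sel]
        lam = result.pooled("lambda_i")[sel] if "lambda_i" in result.draws else None
        nu = result.pooled("nu_i")[sel] if "nu_i" in result.draws else None
        if inputs.age is not None:
            age = np.maximum(inputs.age, 0)  # unknown treated as adult baseline
        else:
            age = np.zeros(inputs.n)
        lp = alpha[sel][:, cell] + beta[:, cell] * inputs.X
        if lam is not None:
            lp += (lam[:, inputs.s_idx] + nu[:, inputs.s_idx] * inputs.X) * age
    else:
        b = result.pooled("beta_i")[sel]
        th = result.pooled("theta_i")[sel]
        om = result.pooled("omega_i")[sel]
        lp = (
            alpha[sel][:, cell]
            + b[:, inputs.s_idx] * inputs.X1
            + th[:, inputs.s_idx] * inputs.X2
            + om[:, inputs.s_idx] * inputs.X1 * inputs.X2
        )
    return lp
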