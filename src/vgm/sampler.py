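"""Adaptive Metropolis-within-Gibbs sampler for hierarchical gamma GLMMs.

The observation model is y_j ~ Gamma(shape = shp_i, rate = shp_i / exp(lp_j)),
so E[y_j] = exp(lp_j). The normal hierarchy over intercepts, slopes and their
means is updated with conjugate Gibbs draws; blocks entering the gamma
likelihood (year-by-species intercepts and slopes, species age effects, gamma
shapes) use vectorized single-site Metropolis updates — valid in parallel
because the likelihood factorizes over disjoint row groups. Scale parameters
use log-scale random walks with half-normal priors; unknown ages are sampled
as discrete latent variables (Gibbs), which targets the same posterior as
analytic marginalization. Proposal scales adapt per component during warmup
only (Robbins-Monro toward 35% acceptance) and are frozen afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, ndtr

LOG_2PI = float(np.log(2.0 * np.pi))

# weakly informative defaults on the standardized scale; the intercept-level
# means (mean log-vagrancy, gamma shape center) live on wider scales
PRIOR_SD_EFFECT_MEAN = 1.0
PRIOR_SD_INTERCEPT_MEAN = 5.0
PRIOR_SD_SIGMA = 1.0
PRIOR_SD_MU_SHAPE = 5.0
PI_BETA_A = 2.0
PI_BETA_B = 2.0


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * LOG_2PI


def _halfnorm_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2


class _Adaptive:
    """Per-component random-walk scales with Robbins-Monro adaptation."""

    def __init__(self, size: int, init: float, target: float = 0.35):
        self.log_scale = np.full(size, np.log(init))
        self.target = target
        self.t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted: np.ndarray) -> None:
        self.t += 1
        rate = min(0.25, 4.0 / np.sqrt(self.t + 10.0))
        self.log_scale += rate * (accepted.astype(float) - self.target)
        np.clip(self.log_scale, -8.0, 4.0, out=self.log_scale)


class _GibbsBase:
    """Shared machinery: data arrays, gamma likelihood pieces, MH kernels."""

    def __init__(self, y, s_idx, t_idx, rng: np.random.Generator):
        self.y = np.asarray(y, float)
        self.log_y = np.log(self.y)
        self.s = np.asarray(s_idx, int)
        self.t = np.asarray(t_idx, int)
        self.S = int(self.s.max()) + 1
        self.T = int(self.t.max()) + 1
        self.n = len(self.y)
        self.rng = rng
        # compress (t, i) to the cells actually present
        raw = self.t * self.S + self.s
        self.cell_codes, self.cell = np.unique(raw, return_inverse=True)
        self.C = len(self.cell_codes)
        self.cell_t = self.cell_codes // self.S
        self.cell_s = self.cell_codes % self.S
        self.rows_per_cell = np.bincount(self.cell, minlength=self.C)
        self.rows_per_species = np.bincount(self.s, minlength=self.S)
        self.scales: dict[str, _Adaptive] = {}

    # -- likelihood pieces ---------------------------------------------------
    def _ll_lp_delta(self, shp_row, lp, lp_new):
        """Row-wise log-likelihood change when lp -> lp_new at fixed shape."""
        return shp_row * ((lp - lp_new) + self.y * (np.exp(-lp) - np.exp(-lp_new)))

    def _ll_full(self, shp_row, lp):
        return (
            shp_row * (np.log(shp_row) - lp)
            - gammaln(shp_row)
            + (shp_row - 1.0) * self.log_y
            - shp_row * self.y * np.exp(-lp)
        )

    # -- kernels -------------------------------------------------------------
    def _mh_group(self, name, values, group_row, n_groups, factor_row,
                  prior_mean, prior_sd, shp_row, lp, adapt, init_scale=0.1):
        """Parallel single-site MH for a vector whose components own disjoint rows."""
        sc = self.scales.setdefault(name, _Adaptive(n_groups, init_scale))
        prop = values + self.rng.normal(size=n_groups) * sc.scale
        dlp = (prop - values)[group_row] * factor_row
        lp_new = lp + dlp
        row_delta = self._ll_lp_delta(shp_row, lp, lp_new)
        delta = np.bincount(group_row, row_delta, minlength=n_groups)
        delta += _norm_logpdf(prop, prior_mean, prior_sd) - _norm_logpdf(values, prior_mean, prior_sd)
        accept = np.log(self.rng.random(n_groups)) < delta
        values = np.where(accept, prop, values)
        lp = np.where(accept[group_row], lp_new, lp)
        if adapt:
            sc.update(accept)
        return values, lp

    def _mh_shape(self, shp, mu_shp, sig_shp, lp, adapt):
        sc = self.scales.setdefault("shp", _Adaptive(self.S, 0.15))
        prop = shp * np.exp(self.rng.normal(size=self.S) * sc.scale)
        row_delta = self._ll_full(prop[self.s], lp) - self._ll_full(shp[self.s], lp)
        delta = np.bincount(self.s, row_delta, minlength=self.S)
        # truncated-normal prior: the Phi(mu/sigma) constant cancels here
        delta += _norm_logpdf(prop, mu_shp, sig_shp) - _norm_logpdf(shp, mu_shp, sig_shp)
        delta += np.log(prop) - np.log(shp)  # log-scale proposal Jacobian
        accept = np.log(self.rng.random(self.S)) < delta
        shp = np.where(accept, prop, shp)
        if adapt:
            sc.update(accept)
        return shp

    def _mh_sigma(self, name, sigma, resid, adapt, prior_sd=PRIOR_SD_SIGMA):
        sc = self.scales.setdefault(name, _Adaptive(1, 0.3))
        prop = sigma * float(np.exp(self.rng.normal() * sc.scale[0]))
        ssq = float(np.sum(resid**2))
        m = len(resid)

        def logpost(s):
            return -m * np.log(s) - 0.5 * ssq / s**2 + _halfnorm_logpdf(s, prior_sd) + np.log(s)

        accept = np.log(self.rng.random()) < logpost(prop) - logpost(sigma)
        if adapt:
            sc.update(np.array([accept]))
        return prop if accept else sigma

    def _conj_group_means(self, obs, group, n_groups, within_sd, prior_mean, prior_sd):
        """Draw group means given normal observations and a normal prior."""
        sums = np.bincount(group, obs, minlength=n_groups)
        counts = np.bincount(group, minlength=n_groups)
        prec = counts / within_sd**2 + 1.0 / prior_sd**2
        mean = (sums / within_sd**2 + prior_mean / prior_sd**2) / prec
        return self.rng.normal(mean, 1.0 / np.sqrt(prec))

    def _conj_scalar_mean(self, obs, within_sd, prior_sd, prior_mean=0.0):
        prec = len(obs) / within_sd**2 + 1.0 / prior_sd**2
        mean = (np.sum(obs) / within_sd**2 + prior_mean / prior_sd**2) / prec
        return float(self.rng.normal(mean, 1.0 / np.sqrt(prec)))

    def _mh_shape_hypers(self, mu_shp, sig_shp, shp, adapt):
        """Joint-ish MH for the truncated-normal shape hyperpriors."""
        for name, which in (("mu_shp", 0), ("sig_shp", 1)):
            sc = self.scales.setdefault(name, _Adaptive(1, 0.2))
            cur = (mu_shp, sig_shp)
            prop = list(cur)
            prop[which] = cur[which] * float(np.exp(self.rng.normal() * sc.scale[0]))

            def logpost(mu, sig):
                ll = np.sum(_norm_logpdf(shp, mu, sig)) - self.S * np.log(ndtr(mu / sig))
                pr = _halfnorm_logpdf(mu, PRIOR_SD_MU_SHAPE) + _halfnorm_logpdf(sig, PRIOR_SD_SIGMA)
                return ll + pr

            delta = logpost(*prop) - logpost(*cur) + np.log(prop[which]) - np.log(cur[which])
            accepted = np.log(self.rng.random()) < delta
            if accepted:
                mu_shp, sig_shp = prop
            if adapt:
                sc.update(np.array([accepted]))
        return float(mu_shp), float(sig_shp)


class SingleDriverSampler(_GibbsBase):
    """Single-driver model: lp = alpha_{t,i} + beta_{t,i} X + lambda_i age + nu_i age X,
    with species-level means, a trait regression on sensitivity
    (delta_i = omega + psi * migration_length_i + eta * breeding_latitude_i),
    and Bayesian imputation of unknown ages."""

    def __init__(self, y, X, s_idx, t_idx, age, trait_design, rng,
                 include_age_terms: bool = True):
        super().__init__(y, s_idx, t_idx, rng)
        self.X = np.asarray(X, float)
        self.age_obs = np.asarray(age, int)  # -1 = unknown
        self.known = self.age_obs >= 0
        self.include_age = include_age_terms
        self.D = np.asarray(trait_design, float)  # (S, P); column 0 is ones
        self.P = self.D.shape[1]
        self._init_state()

    def _init_state(self):
        rng = self.rng
        cell_mean = np.bincount(self.cell, self.log_y, minlength=self.C) / np.maximum(self.rows_per_cell, 1)
        self.alpha = cell_mean + rng.normal(0, 0.05, self.C)
        self.beta = rng.normal(0, 0.02, self.C)
        self.gam = np.bincount(self.s, self.log_y, minlength=self.S) / np.maximum(self.rows_per_species, 1)
        self.mu_g = float(self.gam.mean())
        self.mu_b = rng.normal(0, 0.02, self.S)
        self.lam = rng.normal(0, 0.02, self.S)
        self.nu = rng.normal(0, 0.01, self.S)
        resid_ratio = self.y / np.exp(cell_mean[self.cell])
        var_s = np.bincount(self.s, (resid_ratio - 1.0) ** 2, minlength=self.S) / np.maximum(self.rows_per_species, 1)
        self.shp = np.clip(1.0 / np.maximum(var_s, 1e-3), 0.3, 50.0)
        self.sig_a = 0.2
        self.sig_g = float(np.std(self.gam) + 0.1)
        self.sig_b = 0.1
        self.sig_d = 0.1
        self.sig_l = 0.1
        self.sig_n = 0.05
        self.mu_l = 0.0
        self.mu_n = 0.0
        self.mu_shp = float(np.clip(self.shp.mean(), 0.5, 20.0))
        self.sig_shp = 1.0
        self.w = np.zeros(self.P)
        k1 = np.bincount(self.s[self.known], self.age_obs[self.known], minlength=self.S)
        nk = np.bincount(self.s[self.known], minlength=self.S)
        self.pi = (PI_BETA_A + k1) / (PI_BETA_A + PI_BETA_B + nk)
        self.age = np.where(self.known, np.maximum(self.age_obs, 0),
                            (rng.random(self.n) < self.pi[self.s]).astype(int))
        if not self.include_age:
            self.age = np.zeros(self.n, dtype=int)
        self._recompute_lp()

    def _recompute_lp(self):
        self.lp = self.alpha[self.cell] + self.beta[self.cell] * self.X
        if self.include_age:
            self.lp += (self.lam[self.s] + self.nu[self.s] * self.X) * self.age

    def sweep(self, adapt: bool) -> None:
        shp_row = self.shp[self.s]
        self.alpha, self.lp = self._mh_group(
            "alpha", self.alpha, self.cell, self.C, 1.0,
            self.gam[self.cell_s], self.sig_a, shp_row, self.lp, adapt, 0.1)
        self.beta, self.lp = self._mh_group(
            "beta", self.beta, self.cell, self.C, self.X,
            self.mu_b[self.cell_s], self.sig_b, shp_row, self.lp, adapt, 0.1)
        if self.include_age:
            self.lam, self.lp = self._mh_group(
                "lam", self.lam, self.s, self.S, self.age.astype(float),
                self.mu_l, self.sig_l, shp_row, self.lp, adapt, 0.05)
            self.nu, self.lp = self._mh_group(
                "nu", self.nu, self.s, self.S, self.age * self.X,
                self.mu_n, self.sig_n, shp_row, self.lp, adapt, 0.05)
        self.shp = self._mh_shape(self.shp, self.mu_shp, self.sig_shp, self.lp, adapt)
        shp_row = self.shp[self.s]

        if self.include_age and (~self.known).any():
            lp0 = self.alpha[self.cell] + self.beta[self.cell] * self.X
            add = self.lam[self.s] + self.nu[self.s] * self.X
            l1 = -shp_row * (lp0 + add) - shp_row * self.y * np.exp(-(lp0 + add))
            l0 = -shp_row * lp0 - shp_row * self.y * np.exp(-lp0)
            logit = np.log(self.pi[self.s]) - np.log1p(-self.pi[self.s]) + l1 - l0
            p1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -35, 35)))
            draw = (self.rng.random(self.n) < p1).astype(int)
            self.age = np.where(self.known, self.age, draw)
            self.lp = lp0 + add * self.age
        if self.include_age:
            k1 = np.bincount(self.s, self.age, minlength=self.S)
            self.pi = self.rng.beta(PI_BETA_A + k1, PI_BETA_B + self.rows_per_species - k1)

        # normal hierarchy: conjugate means, MH scales
        self.gam = self._conj_group_means(self.alpha, self.cell_s, self.S,
                                          self.sig_a, self.mu_g, self.sig_g)
        self.mu_g = self._conj_scalar_mean(self.gam, self.sig_g, PRIOR_SD_INTERCEPT_MEAN)
        self.sig_g = self._mh_sigma("sig_g", self.sig_g, self.gam - self.mu_g, adapt)
        self.sig_a = self._mh_sigma("sig_a", self.sig_a, self.alpha - self.gam[self.cell_s], adapt)

        delta_i = self.D @ self.w
        self.mu_b = self._conj_group_means(self.beta, self.cell_s, self.S,
                                           self.sig_b, delta_i, self.sig_d)
        # trait regression (omega, psi, eta): conjugate multivariate normal
        prec = self.D.T @ self.D / self.sig_d**2 + np.eye(self.P) / PRIOR_SD_EFFECT_MEAN**2
        mean = np.linalg.solve(prec, self.D.T @ self.mu_b / self.sig_d**2)
        chol = np.linalg.cholesky(np.linalg.inv(prec))
        self.w = mean + chol @ self.rng.normal(size=self.P)
        delta_i = self.D @ self.w
        self.sig_b = self._mh_sigma("sig_b", self.sig_b, self.beta - self.mu_b[self.cell_s], adapt)
        self.sig_d = self._mh_sigma("sig_d", self.sig_d, self.mu_b - delta_i, adapt)

        if self.include_age:
            self.mu_l = self._conj_scalar_mean(self.lam, self.sig_l, PRIOR_SD_EFFECT_MEAN)
            self.sig_l = self._mh_sigma("sig_l", self.sig_l, self.lam - self.mu_l, adapt)
            self.mu_n = self._conj_scalar_mean(self.nu, self.sig_n, PRIOR_SD_EFFECT_MEAN)
            self.sig_n = self._mh_sigma("sig_n", self.sig_n, self.nu - self.mu_n, adapt)
            self._ridge_moves(adapt)
        self.mu_shp, self.sig_shp = self._mh_shape_hypers(self.mu_shp, self.sig_shp, self.shp, adapt)

    def _ridge_moves(self, adapt: bool) -> None:
        """Directional joint moves along the posterior ridges created by the
        age terms: with mostly-young samples, (alpha_{.,i}, lambda_i) and
        (beta_{.,i}, nu_i) trade off almost one-for-one. Shifting a species'
        intercepts (and gamma_i) down while shifting lambda_i up leaves
        young-bird rows untouched, so the move is informed only by adult rows
        and traverses the ridge that single-site updates crawl along."""
        shp_row = self.shp[self.s]
        adult = 1.0 - self.age

        # (alpha, gamma) vs lambda
        sc = self.scales.setdefault("ridge_lam", _Adaptive(self.S, 0.05))
        d = self.rng.normal(size=self.S) * sc.scale
        lp_new = self.lp - d[self.s] * adult
        delta = np.bincount(self.s, self._ll_lp_delta(shp_row, self.lp, lp_new), minlength=self.S)
        delta += _norm_logpdf(self.gam - d, self.mu_g, self.sig_g) - _norm_logpdf(self.gam, self.mu_g, self.sig_g)
        delta += _norm_logpdf(self.lam + d, self.mu_l, self.sig_l) - _norm_logpdf(self.lam, self.mu_l, self.sig_l)
        accept = np.log(self.rng.random(self.S)) < delta
        step = np.where(accept, d, 0.0)
        self.gam -= step
        self.lam += step
        self.alpha -= step[self.cell_s]
        self.lp = np.where(accept[self.s], lp_new, self.lp)
        if adapt:
            sc.update(accept)

        # (beta, mu_beta_i) vs nu
        delta_i = self.D @ self.w
        sc = self.scales.setdefault("ridge_nu", _Adaptive(self.S, 0.05))
        d = self.rng.normal(size=self.S) * sc.scale
        lp_new = self.lp - d[self.s] * adult * self.X
        delta = np.bincount(self.s, self._ll_lp_delta(shp_row, self.lp, lp_new), minlength=self.S)
        delta += _norm_logpdf(self.mu_b - d, delta_i, self.sig_d) - _norm_logpdf(self.mu_b, delta_i, self.sig_d)
        delta += _norm_logpdf(self.nu + d, self.mu_n, self.sig_n) - _norm_logpdf(self.nu, self.mu_n, self.sig_n)
        accept = np.log(self.rng.random(self.S)) < delta
        step = np.where(accept, d, 0.0)
        self.mu_b -= step
        self.nu += step
        self.beta -= step[self.cell_s]
        self.lp = np.where(accept[self.s], lp_new, self.lp)
        if adapt:
            sc.update(accept)

        # global translations along the top-level effect directions: shift a
        # whole level and its mean together so only the likelihood (and the
        # top prior) decides, decoupling the mean from slow child mixing
        for p in range(self.P):
            self._global_shift(f"shift_w{p}", self.D[self.s, p] * self.X, adapt,
                               level="w", column=p)
        self._global_shift("shift_lambda", self.age.astype(float), adapt, level="lambda")
        self._global_shift("shift_nu", self.age * self.X, adapt, level="nu")

    def _global_shift(self, name: str, factor_row, adapt: bool, level: str,
                      column: int = 0) -> None:
        sc = self.scales.setdefault(name, _Adaptive(1, 0.02))
        d = float(self.rng.normal() * sc.scale[0])
        shp_row = self.shp[self.s]
        lp_new = self.lp + d * factor_row
        delta = float(np.sum(self._ll_lp_delta(shp_row, self.lp, lp_new)))
        if level == "w":
            top = self.w[column]
        elif level == "lambda":
            top = self.mu_l
        else:
            top = self.mu_n
        # N(0, 1) prior kernel on the shifted top-level mean
        delta += float(_halfnorm_logpdf(top + d, PRIOR_SD_EFFECT_MEAN)
                       - _halfnorm_logpdf(top, PRIOR_SD_EFFECT_MEAN))
        accept = np.log(self.rng.random()) < delta
        if accept:
            if level == "w":
                self.w[column] += d
                self.mu_b += d * self.D[:, column]
                self.beta += d * self.D[self.cell_s, column]
            elif level == "lambda":
                self.mu_l += d
                self.lam += d
            else:
                self.mu_n += d
                self.nu += d
            self.lp = lp_new
        if adapt:
            sc.update(np.array([accept]))

    def snapshot(self) -> dict:
        out = {
            "omega": self.w[0],
            "mu_gamma": self.mu_g,
            "mu_shp": self.mu_shp,
            "sigma_shp": self.sig_shp,
            "sigma_alpha": self.sig_a,
            "sigma_gamma": self.sig_g,
            "sigma_beta": self.sig_b,
            "sigma_delta": self.sig_d,
            "gamma_i": self.gam.copy(),
            "mu_beta_i": self.mu_b.copy(),
            "shp_i": self.shp.copy(),
            "alpha_cell": self.alpha.copy(),
            "beta_cell": self.beta.copy(),
        }
        if self.P > 1:
            out["psi"] = self.w[1]
        if self.P > 2:
            out["eta"] = self.w[2]
        if self.include_age:
            out.update(
                mu_lambda=self.mu_l, mu_nu=self.mu_n,
                sigma_lambda=self.sig_l, sigma_nu=self.sig_n,
                lambda_i=self.lam.copy(), nu_i=self.nu.copy(), pi_i=self.pi.copy(),
            )
        return out


class InteractionSampler(_GibbsBase):
    """Two-driver interaction model: lp = alpha_{t,i} + beta_i X1 + theta_i X2
    + omegaI_i X1 X2, with species-level normal hierarchies on every slope and
    a two-level intercept hierarchy (alpha_{t,i} -> mu_alpha_i -> gamma)."""

    def __init__(self, y, X1, X2, s_idx, t_idx, rng):
        super().__init__(y, s_idx, t_idx, rng)
        self.X1 = np.asarray(X1, float)
        self.X2 = np.asarray(X2, float)
        self.X12 = self.X1 * self.X2
        self._init_state()

    def _init_state(self):
        rng = self.rng
        cell_mean = np.bincount(self.cell, self.log_y, minlength=self.C) / np.maximum(self.rows_per_cell, 1)
        self.alpha = cell_mean + rng.normal(0, 0.05, self.C)
        self.mu_a = np.bincount(self.s, self.log_y, minlength=self.S) / np.maximum(self.rows_per_species, 1)
        self.gam = float(self.mu_a.mean())
        self.b = rng.normal(0, 0.02, self.S)
        self.th = rng.normal(0, 0.02, self.S)
        self.om = rng.normal(0, 0.01, self.S)
        resid_ratio = self.y / np.exp(cell_mean[self.cell])
        var_s = np.bincount(self.s, (resid_ratio - 1.0) ** 2, minlength=self.S) / np.maximum(self.rows_per_species, 1)
        self.shp = np.clip(1.0 / np.maximum(var_s, 1e-3), 0.3, 50.0)
        self.mu_b = self.mu_t = self.mu_o = 0.0
        self.sig_a = 0.2
        self.sig_mua = float(np.std(self.mu_a) + 0.1)
        self.sig_b = self.sig_t = 0.1
        self.sig_o = 0.05
        self.mu_shp = float(np.clip(self.shp.mean(), 0.5, 20.0))
        self.sig_shp = 1.0
        self._recompute_lp()

    def _recompute_lp(self):
        self.lp = (self.alpha[self.cell] + self.b[self.s] * self.X1
                   + self.th[self.s] * self.X2 + self.om[self.s] * self.X12)

    def sweep(self, adapt: bool) -> None:
        shp_row = self.shp[self.s]
        self.alpha, self.lp = self._mh_group(
            "alpha", self.alpha, self.cell, self.C, 1.0,
            self.mu_a[self.cell_s], self.sig_a, shp_row, self.lp, adapt, 0.1)
        self.b, self.lp = self._mh_group(
            "b", self.b, self.s, self.S, self.X1, self.mu_b, self.sig_b,
            shp_row, self.lp, adapt, 0.05)
        self.th, self.lp = self._mh_group(
            "th", self.th, self.s, self.S, self.X2, self.mu_t, self.sig_t,
            shp_row, self.lp, adapt, 0.05)
        self.om, self.lp = self._mh_group(
            "om", self.om, self.s, self.S, self.X12, self.mu_o, self.sig_o,
            shp_row, self.lp, adapt, 0.05)
        self.shp = self._mh_shape(self.shp, self.mu_shp, self.sig_shp, self.lp, adapt)

        self.mu_a = self._conj_group_means(self.alpha, self.cell_s, self.S,
                                           self.sig_a, self.gam, self.sig_mua)
        self.gam = self._conj_scalar_mean(self.mu_a, self.sig_mua, PRIOR_SD_INTERCEPT_MEAN)
        self.sig_mua = self._mh_sigma("sig_mua", self.sig_mua, self.mu_a - self.gam, adapt)
        self.sig_a = self._mh_sigma("sig_a", self.sig_a, self.alpha - self.mu_a[self.cell_s], adapt)
        self.mu_b = self._conj_scalar_mean(self.b, self.sig_b, PRIOR_SD_EFFECT_MEAN)
        self.sig_b = self._mh_sigma("sig_b", self.sig_b, self.b - self.mu_b, adapt)
        self.mu_t = self._conj_scalar_mean(self.th, self.sig_t, PRIOR_SD_EFFECT_MEAN)
        self.sig_t = self._mh_sigma("sig_t", self.sig_t, self.th - self.mu_t, adapt)
        self.mu_o = self._conj_scalar_mean(self.om, self.sig_o, PRIOR_SD_EFFECT_MEAN)
        self.sig_o = self._mh_sigma("sig_o", self.sig_o, self.om - self.mu_o, adapt)
        self.mu_shp, self.sig_shp = self._mh_shape_hypers(self.mu_shp, self.sig_shp, self.shp, adapt)

    def snapshot(self) -> dict:
        return {
            "mu_beta": self.mu_b,
            "mu_theta": self.mu_t,
            "mu_omega": self.mu_o,
            "gamma": self.gam,
            "mu_shp": self.mu_shp,
            "sigma_shp": self.sig_shp,
            "sigma_alpha": self.sig_a,
            "sigma_mu_alpha": self.sig_mua,
            "sigma_beta": self.sig_b,
            "sigma_theta": self.sig_t,
            "sigma_omega": self.sig_o,
            "beta_i": self.b.copy(),
            "theta_i": self.th.copy(),
            "omega_i": self.om.copy(),
            "mu_alpha_i": self.mu_a.copy(),
            "shp_i": self.shp.copy(),
            "alpha_cell": self.alpha.copy(),
        }


def run_chain(sampler, n_warmup: int, n_draws: int, thin: int = 1) -> dict[str, np.ndarray]:
    """Run one chain: adapt during warmup, then collect ``n_draws`` snapshots."""
    for _ in range(n_warmup):
        sampler.sweep(adapt=True)
    collected: dict[str, list] = {}
    for it in range(n_draws * thin):
        sampler.sweep(adapt=False)
        if it % thin == 0:
            for k, v in sampler.snapshot().items():
                collected.setdefault(k, []).append(v)
    return {k: np.asarray(v) for k, v in collected.items()}
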