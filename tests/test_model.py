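import numpy as np
import pandas as pd
import pytest

from vgm.model import (
    ModelInputs,
    ModelSpec,
    PosteriorDraws,
    bayesian_r2,
    build_inputs,
    fit,
    posterior_predictive_check,
    predicted_change_percent,
    summarize,
)


def _draws_result(draws: dict, species=("A", "B")) -> PosteriorDraws:
    return PosteriorDraws(
        draws=draws, species=list(species),
        diagnostics=pd.DataFrame(), converged=True,
    )


class TestBuildInputs:
    def _table(self, n_species=3, n_years=4, rows_per=5):
        rows = []
        rid = 0
        for i in range(n_species):
            for t in range(n_years):
                for _ in range(rows_per):
                    rows.append(
                        {
                            "record_id": f"R{rid}",
                            "species_code": f"SP{i:03d}",
                            "date": pd.Timestamp(f"{2001 + t}-09-10"),
                            "vagrancy_km": 50.0 + rid % 7,
                            "geomag_z": 0.1 * (rid % 5 - 2),
                            "solar_z": 0.1 * (rid % 3 - 1),
                            "age_class": ["adult", "young", "unknown"][rid % 3],
                            "migration_length_z": float(i - 1),
                            "breeding_latitude_z": float(1 - i),
                        }
                    )
                    rid += 1
        return pd.DataFrame(rows)

    def test_index_arithmetic(self):
        from vgm.sampler import SingleDriverSampler

        spec = ModelSpec()
        inputs = build_inputs(self._table(), spec)
        assert len(inputs.species) == 3
        assert len(inputs.years) == 4
        sampler = SingleDriverSampler(
            inputs.y, inputs.X, inputs.s_idx, inputs.t_idx, inputs.age,
            inputs.trait_design, np.random.default_rng(0),
        )
        assert sampler.C == 12  # 3 species x 4 years intercept cells

    def test_unknown_age_rows_retained_for_imputation(self):
        inputs = build_inputs(self._table(), ModelSpec())
        assert (inputs.age == -1).sum() > 0

    def test_zero_vagrancy_is_rejected(self):
        table = self._table()
        table.loc[0, "vagrancy_km"] = 0.0
        with pytest.raises(ValueError, match="floor"):
            build_inputs(table, ModelSpec())

    def test_out_of_range_rows_dropped(self):
        table = self._table()
        table["excluded_out_of_range"] = False
        table.loc[:4, "excluded_out_of_range"] = True
        inputs = build_inputs(table, ModelSpec())
        assert inputs.n == len(table) - 5

    def test_interaction_spec_disables_age_terms(self):
        spec = ModelSpec(form="interaction", include_age_terms=True)
        assert not spec.include_age_terms


class TestSummarize:
    def test_median_of_symmetric_draws(self):
        res = _draws_result({"omega": np.array([[-1.0, 0.0, 1.0]])})
        assert summarize(res, "omega")["median"] == 0.0

    def test_all_positive_draws(self):
        res = _draws_result({"omega": np.abs(np.random.default_rng(0).normal(size=(2, 200))) + 0.01})
        s = summarize(res, "omega")
        assert s["tail_prob"] == 1.0
        assert s["tail_side"] == "p(>0)"

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(1).standard_normal((4, 20_000))
        s = summarize(_draws_result({"omega": draws}), "omega")
        assert s["cri_low"] == pytest.approx(-1.96, abs=0.05)
        assert s["cri_high"] == pytest.approx(1.96, abs=0.05)

    def test_unknown_parameter_lists_available(self):
        res = _draws_result({"omega": np.zeros((1, 3))})
        with pytest.raises(KeyError, match="omega"):
            summarize(res, "nope")


class TestPredictedChange:
    @pytest.mark.parametrize(
        "effect,delta,expected",
        [(0.109, 2.0, 24.36), (0.0, 2.0, 0.0), (-0.023, 2.0, -4.496)],
    )
    def test_log_link_change(self, effect, delta, expected):
        assert predicted_change_percent(effect, delta) == pytest.approx(expected, abs=0.01)


class TestBayesianR2:
    def _inputs(self, y, X1, X2, s):
        return ModelInputs(
            y=np.asarray(y, float), s_idx=np.asarray(s), t_idx=np.zeros(len(y), int),
            species=["A", "B"], years=[2001], X1=np.asarray(X1, float),
            X2=np.asarray(X2, float),
        )

    def test_zero_effects_give_zero(self):
        rng = np.random.default_rng(0)
        n = 40
        s = np.repeat([0, 1], n // 2)
        inputs = self._inputs(rng.gamma(2, 1, n), rng.normal(size=n), rng.normal(size=n), s)
        draws = {
            "beta_i": np.zeros((1, 5, 2)),
            "theta_i": np.zeros((1, 5, 2)),
            "omega_i": np.zeros((1, 5, 2)),
        }
        out = bayesian_r2(_draws_result(draws), inputs)
        assert out["cross_species_median"] == 0.0

    def test_exact_fit_gives_one(self):
        n = 40
        s = np.repeat([0, 1], n // 2)
        X1 = np.linspace(-1, 1, n)
        X2 = np.zeros(n)
        y = 0.5 * X1  # equals g_rep exactly when beta=0.5
        draws = {
            "beta_i": np.full((1, 5, 2), 0.5),
            "theta_i": np.zeros((1, 5, 2)),
            "omega_i": np.zeros((1, 5, 2)),
        }
        out = bayesian_r2(_draws_result(draws), self._inputs(y, X1, X2, s))
        assert out["cross_species_median"] == pytest.approx(1.0)

    def test_requires_interaction_draws(self):
        res = _draws_result({"omega": np.zeros((1, 3))})
        with pytest.raises(ValueError, match="interaction"):
            bayesian_r2(res, self._inputs([1.0, 2.0], [0, 0], [0, 0], [0, 1]))


class TestFitSmoke:
    def test_single_driver_fit_recovers_scale_and_converges(self, fitted_single):
        result, truth = fitted_single
        # intercept level: mean log-vagrancy should sit near the generative value
        s = summarize(result, "mu_gamma")
        assert s["cri_low"] - 0.5 < truth["params"]["mu_gamma"] < s["cri_high"] + 0.5
        assert (result.diagnostics["rhat"] < 1.2).all()
        om = summarize(result, "omega")
        assert om["cri_low"] < truth["params"]["omega_true"] < om["cri_high"]

    def test_draws_long_format(self, fitted_single):
        result, _ = fitted_single
        frame = result.to_frame()
        assert {"chain", "iteration", "parameter", "value"} <= set(frame.columns)
        assert (frame["parameter"] == "omega").sum() == 2 * 800

    def test_ppc_self_consistency(self, fitted_single):
        result, _ = fitted_single
        ppc = posterior_predictive_check(result, statistic="mean", max_draws=100, seed=1)
        # model-generated data: tail probabilities should not be extreme
        assert ppc["tail_prob"].between(0.01, 0.99).mean() >= 0.8
        assert abs(ppc["tail_prob"].mean() - 0.5) < 0.25


def test_chains_below_two_rejected():
    with pytest.raises(ValueError, match="chains"):
        ModelSpec(chains=1)
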