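"""Model assembly, Gibbs sampling, recovery, and the Gaussian limit."""

import numpy as np
import pytest

import alimix as am
from alimix.blmm import DEFAULT_GRAPH, ModelSpec
from alimix.simulate import standardized_true_beta


def _complete_data(n_sites=6, n_per_site=25, seed=0, **truth_kwargs):
    truth = am.SyntheticTruth(missing_rate=0.0, censor_rate=0.0, **truth_kwargs)
    frame, truth = am.generate(n_sites, n_per_site, truth, seed=seed)
    data, scaling = am.standardize(frame, am.PREDICTORS)
    return frame, truth, data, scaling


class TestBuildModel:
    def test_parameter_count_complete_data(self):
        _, _, data, _ = _complete_data()
        model = am.build_model(data)
        p, J, K = len(am.PREDICTORS), data.n_sites, model.spec.n_spline_basis
        plain_submodels = sum(
            1 for v in DEFAULT_GRAPH.values() if v != am.SEASONAL
        )
        expected = (
            p + 1 + 1 + J + 3            # beta, tau, global intercept, sites, scales+df
            + 3 * plain_submodels        # coef, sigma_p, nu_p each
            + (K + 4)                    # seasonal: gamma, b, sigma_b, sigma_p, nu_p
        )
        assert model.n_cells == 0
        assert model.n_parameters == expected

    def test_one_censored_cell_adds_one_bounded_parameter(self):
        _, _, data, _ = _complete_data()
        base = am.build_model(data).n_parameters
        j = data.predictors.index("Al_d")
        data.censored_mask[0, j] = True
        data.censor_bounds[0, j] = data.X[0, j]
        model = am.build_model(data)
        assert model.n_parameters == base + 1
        assert model.n_cells == 1
        assert model.cell_censored.all()

    def test_cyclic_graph_rejected(self):
        _, _, data, _ = _complete_data()
        graph = dict(DEFAULT_GRAPH)
        graph["DOC"] = "Al_d"  # Al_d <- DOC <- Al_d
        with pytest.raises(ValueError, match="cycle"):
            am.build_model(data, ModelSpec(predictors=list(data.predictors), graph=graph))

    def test_missing_cells_without_submodel_rejected(self):
        _, _, data, _ = _complete_data()
        graph = {k: v for k, v in DEFAULT_GRAPH.items() if k != "color"}
        j = data.predictors.index("color")
        data.missing_mask[0, j] = True
        data.X[0, j] = np.nan
        with pytest.raises(ValueError, match="color"):
            am.build_model(data, ModelSpec(predictors=list(data.predictors), graph=graph))

    def test_invalid_masks_rejected(self):
        _, _, data, _ = _complete_data()
        data.missing_mask[0, 0] = True
        data.censored_mask[0, 0] = True
        with pytest.raises(ValueError, match="both"):
            data.validate()


class TestFit:
    def test_determinism(self):
        frame, _ = am.generate(4, 12, seed=8)
        data, _ = am.standardize(frame, am.PREDICTORS)
        model = am.build_model(data)
        kwargs = dict(chains=2, draws_per_chain=40, warmup=40, seed=5)
        with np.errstate(all="ignore"):
            a = am.fit(model, **kwargs)
            b = am.fit(am.build_model(data), **kwargs)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])
        assert np.array_equal(a.imputed, b.imputed)

    def test_seed_required(self):
        frame, _ = am.generate(4, 12, seed=8)
        data, _ = am.standardize(frame, am.PREDICTORS)
        with pytest.raises(ValueError, match="seed"):
            am.fit(am.build_model(data))

    def test_recovery_complete_data_strong_effect(self):
        """The dominant coefficient is recovered from complete data."""
        truth_in = am.SyntheticTruth(missing_rate=0.0, censor_rate=0.0)
        truth_in.beta = dict(truth_in.beta, Al_d=0.8)
        truth_in.sigma, truth_in.nu = 0.3, 30.0
        frame, truth = am.generate(15, 40, truth_in, seed=77)  # n = 600
        data, scaling = am.standardize(frame, am.PREDICTORS)
        result = am.fit(
            am.build_model(data), chains=2, draws_per_chain=400, warmup=400, seed=78
        )
        target = standardized_true_beta(truth, scaling)["Al_d"]
        j = result.predictors.index("Al_d")
        lo, hi = np.quantile(result.stacked("beta")[:, j], [0.025, 0.975])
        assert lo <= target <= hi

    def test_censored_draws_respect_bounds(self, fitted):
        result = fitted["result"]
        assert result.cell_censored.any()
        assert result.censoring_violations() == 0

    def test_most_coefficients_covered(self, fitted):
        result, truth, scaling = (
            fitted["result"], fitted["truth"], fitted["scaling"],
        )
        target = standardized_true_beta(truth, scaling)
        beta = result.stacked("beta")
        covered = 0
        for j, name in enumerate(result.predictors):
            lo, hi = np.quantile(beta[:, j], [0.025, 0.975])
            covered += lo <= target[name] <= hi
        assert covered >= 11  # ~95% nominal coverage over 13 coefficients

    def test_shrinkage_prior_pulls_toward_zero(self):
        frame, _ = am.generate(5, 15, am.SyntheticTruth(missing_rate=0.0, censor_rate=0.0), seed=13)
        data, _ = am.standardize(frame, am.PREDICTORS)
        kwargs = dict(chains=2, draws_per_chain=100, warmup=100, seed=14)
        with np.errstate(all="ignore"):
            default = am.fit(am.build_model(data), **kwargs)
            tight_spec = ModelSpec(
                predictors=list(data.predictors), tau_prior_scale=1e-3
            )
            tight = am.fit(am.build_model(data, tight_spec), **kwargs)
        m_default = np.abs(np.median(default.stacked("beta"), axis=0)).sum()
        m_tight = np.abs(np.median(tight.stacked("beta"), axis=0)).sum()
        assert m_tight < m_default

    def test_quantile_ordering(self, fitted):
        summary = fitted["result"].summary(["beta", "sigma", "nu", "alpha_site"])
        assert (summary["Q2.5"] <= summary["Q50"]).all()
        assert (summary["Q50"] <= summary["Q97.5"]).all()

    def test_diagnostics_reported(self, fitted):
        diag = fitted["result"].diagnostics
        assert diag["divergences"] == 0
        assert np.isfinite(diag["max_rhat"])
        assert diag["min_ess"] > 10


class TestGaussianLimit:
    def test_matches_penalized_least_squares(self):
        """With nu fixed large the posterior matches ridge regression."""
        truth_in = am.SyntheticTruth(missing_rate=0.0, censor_rate=0.0)
        truth_in.sigma, truth_in.nu = 0.4, 1000.0
        frame, _ = am.generate(8, 40, truth_in, seed=21)
        data, _ = am.standardize(frame, am.PREDICTORS)
        spec = ModelSpec(predictors=list(data.predictors), nu_fixed=1000.0)
        result = am.fit(
            am.build_model(data, spec), chains=2, draws_per_chain=400, warmup=400, seed=22
        )
        beta = result.stacked("beta")
        med = np.median(beta, axis=0)
        sd = np.std(beta, axis=0)
        # penalized LS with the fitted scales: joint solve over intercept,
        # penalized site effects, and ridge-penalized coefficients
        sigma2 = np.median(result.stacked("sigma")) ** 2
        tau2 = np.median(result.stacked("tau")) ** 2
        sa2 = np.median(result.stacked("sigma_alpha")) ** 2
        X, y, site = data.X, data.y, data.site_index
        J, p = data.n_sites, X.shape[1]
        Z = np.zeros((len(y), J))
        Z[np.arange(len(y)), site] = 1.0
        D = np.column_stack([np.ones(len(y)), Z, X])
        penalty = np.concatenate([[1e-8], np.full(J, sigma2 / sa2), np.full(p, sigma2 / tau2)])
        coef = np.linalg.solve(D.T @ D + np.diag(penalty), D.T @ y)
        ridge_beta = coef[1 + J:]
        assert np.all(np.abs(med - ridge_beta) < 2 * sd)


class TestCoefficientTable:
    def test_sorted_by_absolute_median(self, fitted):
        table = am.coefficient_table(fitted["result"])
        magnitudes = np.abs(table["Q50"].to_numpy())
        assert (np.diff(magnitudes) <= 1e-12).all()
        assert set(table["predictor"]) == set(am.PREDICTORS)

    def test_known_median_ordering(self):
        # medians {0.79, -0.33, 0.20} must order Al_d, DOC, Ti_d
        draws = {
            "beta": np.tile(np.array([0.79, -0.33, 0.20]), (1, 4, 1)),
            "sigma": np.ones((1, 4)),
        }
        result = am.PosteriorResult(
            draws=draws,
            predictors=["Al_d", "DOC", "Ti_d"],
            site_labels=["a"],
            cell_rows=np.empty(0, int),
            cell_cols=np.empty(0, int),
            cell_censored=np.empty(0, bool),
            cell_bounds=np.empty(0),
            imputed=np.empty((1, 4, 0)),
            diagnostics={},
            spec=ModelSpec(predictors=["Al_d", "DOC", "Ti_d"], graph={}),
        )
        table = am.coefficient_table(result)
        assert list(table["predictor"]) == ["Al_d", "DOC", "Ti_d"]

    def test_single_draw_quantiles_collapse(self):
        draws = {
            "beta": np.full((1, 1, 2), 0.5),
            "sigma": np.ones((1, 1)),
        }
        result = am.PosteriorResult(
            draws=draws,
            predictors=["Al_d", "DOC"],
            site_labels=["a"],
            cell_rows=np.empty(0, int),
            cell_cols=np.empty(0, int),
            cell_censored=np.empty(0, bool),
            cell_bounds=np.empty(0),
            imputed=np.empty((1, 1, 0)),
            diagnostics={},
            spec=ModelSpec(predictors=["Al_d", "DOC"], graph={}),
        )
        table = am.coefficient_table(result)
        assert (table["Q2.5"] == table["Q50"]).all()
        assert (table["Q50"] == table["Q97.5"]).all()


class TestPersistence:
    def test_save_load_round_trip(self, fitted, tmp_path):
        from alimix.blmm import load_posterior, save_posterior

        result = fitted["result"]
        save_posterior(result, tmp_path / "p.npz", tmp_path / "p.json")
        back = load_posterior(tmp_path / "p.npz", tmp_path / "p.json")
        assert np.array_equal(back.stacked("beta"), result.stacked("beta"))
        assert back.predictors == result.predictors
        assert back.spec.n_spline_basis == result.spec.n_spline_basis
        assert back.censoring_violations() == 0
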