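"""Design construction, PCA, subsampling, and the hierarchical fits."""

import numpy as np
import pandas as pd
import pytest

from wolfmove.model import (
    CATEGORICAL_LEVELS,
    ModelSpec,
    _gaussian_logp_grad_factory,
    _make_layout,
    _zib_logp_grad_factory,
    assign_grid_cells,
    assign_period,
    build_design,
    compress_boundary_ones,
    fit_model,
    posterior_predict,
    refuge_pca,
    subsample_two_thirds,
)


class TestPeriodsAndGrid:
    @pytest.mark.parametrize(
        "date,period",
        [
            ("2010-03-15", "mating"),
            ("2010-02-01", "mating"),
            ("2010-04-30", "mating"),
            ("2010-07-01", "breeding"),
            ("2010-10-31", "breeding"),
            ("2010-11-01", "nonreproductive"),
            ("2010-01-02", "nonreproductive"),
        ],
    )
    def test_month_to_period(self, date, period):
        assert assign_period(pd.Timestamp(date)) == period

    def test_grid_cell_from_midpoint(self):
        df = pd.DataFrame({"mid_x_km": [0.4, 1.7, 1.7], "mid_y_km": [0.9, 0.1, 1.99]})
        cells = assign_grid_cells(df)
        assert list(cells) == ["c0_0", "c1_0", "c1_1"]


class TestSubsampling:
    def make(self, n_per=9, n_ind=4, months=(1, 2, 3)):
        rows = []
        for i in range(n_ind):
            for m in months:
                base = pd.Timestamp(2010, m, 1)
                for d in range(n_per):
                    rows.append(
                        {"individual_id": f"W{i}", "track_date": base + pd.Timedelta(hours=d)}
                    )
        return pd.DataFrame(rows)

    def test_stratum_of_three_keeps_two(self):
        df = self.make(n_per=3, n_ind=1, months=(5,))
        out = subsample_two_thirds(df, seed=0)
        assert len(out) == 2

    def test_overall_fraction_close_to_two_thirds(self):
        df = self.make(n_per=50, n_ind=8, months=(1, 2, 3, 4))
        out = subsample_two_thirds(df, seed=1)
        assert abs(len(out) / len(df) - 2 / 3) < 0.01

    def test_deterministic_under_seed(self):
        df = self.make()
        a = subsample_two_thirds(df, seed=7)
        b = subsample_two_thirds(df, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_proportions_preserved_per_individual(self):
        df = self.make(n_per=30)
        out = subsample_two_thirds(df, seed=2)
        frac = out.groupby("individual_id").size() / df.groupby("individual_id").size()
        assert np.allclose(frac, 2 / 3, atol=0.01)


class TestRefugePCA:
    def make_covariates(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(n)  # extent/cohesion axis
        shape = rng.standard_normal(n)  # shape complexity axis
        return pd.DataFrame(
            {
                "refuge_cover_pct": 50 + 20 * latent + rng.normal(0, 2, n),
                "mean_cohesion": 0.5 + 0.15 * latent + rng.normal(0, 0.02, n),
                "mean_patch_size": 0.1 + 0.05 * latent + rng.normal(0, 0.01, n),
                "patch_density": 5 - 1.5 * latent + rng.normal(0, 0.3, n),
                "mean_fdi": 1.3 + 0.1 * shape + rng.normal(0, 0.01, n),
            }
        )

    def test_dim1_loads_positively_on_cover_and_cohesion(self):
        res = refuge_pca(self.make_covariates())
        assert res.loadings.loc["refuge_cover_pct", "refuge_dim1"] > 0
        assert res.loadings.loc["mean_cohesion", "refuge_dim1"] > 0
        assert res.loadings.loc["patch_density", "refuge_dim1"] < 0

    def test_variance_explained_sums_to_one_over_all_components(self):
        res = refuge_pca(self.make_covariates(), n_components=5)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_latent_factor_dominates_dim1(self):
        res = refuge_pca(self.make_covariates())
        assert res.variance_explained[0] > 0.5

    def test_zero_variance_column_rejected(self):
        df = self.make_covariates()
        df["mean_fdi"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            refuge_pca(df)

    def test_zero_patch_rows_imputed_at_limits(self):
        df = self.make_covariates(n=50)
        df.loc[:4, ["mean_patch_size", "mean_cohesion", "mean_fdi"]] = np.nan
        res = refuge_pca(df)
        assert np.isfinite(res.scores.to_numpy()).all()


class TestDesign:
    def records(self, n=200, seed=0):
        from wolfmove.validation import recovery_records

        rec, _ = recovery_records(seed=seed, n_individuals=5, days=n // 5)
        return rec

    def test_continuous_columns_standardized(self):
        rec = self.records()
        spec = ModelSpec(response="daily_distance")
        X, meta = build_design(rec, spec, standardize=True)
        for name in ("pop_density", "tri", "refuge_dim1"):
            col = X[:, meta.column_names.index(name)]
            assert abs(col.mean()) < 1e-8
            assert abs(col.std() - 1) < 1e-8

    def test_interaction_parents_enforced(self):
        with pytest.raises(ValueError, match="parent"):
            ModelSpec(response="daily_distance", fixed_terms=("tri",), interactions=("tri x pop_density",))

    def test_unknown_categorical_level_rejected(self):
        rec = self.records()
        rec.loc[rec.index[0], "sex"] = "unknown"
        with pytest.raises(ValueError, match="unknown levels"):
            build_design(rec, ModelSpec(response="daily_distance"))

    def test_override_recomputes_interaction_columns(self):
        rec = self.records()
        spec = ModelSpec(response="daily_distance")
        X0, meta = build_design(rec, spec, standardize=True)
        X1, _ = build_design(rec, spec, meta=meta, overrides={"pop_density": 0.0})
        j = meta.column_names.index("pop_density x settlement_density")
        assert np.allclose(X1[:, j], 0.0)
        k = meta.column_names.index("settlement_density")
        assert np.allclose(X1[:, k], X0[:, k])

    def test_boundary_ones_compressed_only_at_boundary(self):
        y = np.array([0.0, 0.5, 1.0, 0.99])
        out = compress_boundary_ones(y)
        assert out[0] == 0.0 and out[1] == 0.5 and out[3] == 0.99
        assert out[2] == pytest.approx((1.0 * 3 + 0.5) / 4)
        assert out[2] < 1.0


class TestLogPosteriors:
    def _check_grad(self, factory, y):
        rng = np.random.default_rng(0)
        n, p, ni, nc = 40, 3, 4, 5
        X = rng.standard_normal((n, p))
        X[:, 0] = 1
        ind = rng.integers(0, ni, n)
        cell = rng.integers(0, nc, n)
        prior_sd = np.full(p, 1.0)
        prior_sd[0] = 10.0
        tail = "log_sigma_resid" if factory is _gaussian_logp_grad_factory else "log_phi"
        slices = _make_layout(p, ni, nc, tail)
        lg = factory(X, y, ind, cell, slices, prior_sd, 2.5)
        theta = rng.standard_normal(slices["__dim__"].stop) * 0.3
        lp, g = lg(theta)
        eps = 1e-6
        for k in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            num = (lg(tp)[0] - lg(tm)[0]) / (2 * eps)
            assert g[k] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_gaussian_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        self._check_grad(_gaussian_logp_grad_factory, rng.standard_normal(40) + 2.0)

    def test_zib_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        self._check_grad(_zib_logp_grad_factory, rng.uniform(0.05, 0.95, 40))


class TestFits:
    def test_gaussian_posterior_recovers_truth(self, gauss_fit, gauss_records):
        _, truth = gauss_records
        summ = gauss_fit.summary()
        for name, true_val in truth.beta.items():
            lo, hi = summ.loc[name, "q2.5"], summ.loc[name, "q97.5"]
            # generous envelope: the small fixture fit should land near truth
            assert lo - 0.3 < true_val < hi + 0.3

    def test_gaussian_residual_mean_near_zero(self, gauss_fit):
        from wolfmove.inference import _predict_draws

        rec_n = gauss_fit.X.shape[0]
        pred = np.median(
            gauss_fit.linear_predictor_draws(gauss_fit.X, gauss_fit.ind_idx, gauss_fit.cell_idx), axis=0
        )
        resid = gauss_fit.y - pred
        assert abs(resid.mean()) < 0.1

    def test_rhat_reported_for_all_parameters(self, gauss_fit):
        rh = gauss_fit.rhat()
        assert set(gauss_fit.meta.column_names) <= set(rh.index)
        assert rh.notna().all()
        assert rh.max() < 1.2  # reduced-MCMC fixture; reference runs use 4x4000

    def test_all_zero_responses_degenerate_pi(self):
        n = 300
        df = pd.DataFrame(
            {
                "straightness": np.zeros(n),
                "refuge_dim1": np.random.default_rng(0).standard_normal(n),
                "individual_id": ["a"] * (n // 2) + ["b"] * (n - n // 2),
                "grid_cell_id": "c0",
                "track_date": "2010-06-01",
            }
        )
        spec = ModelSpec(response="straightness", fixed_terms=("refuge_dim1",), interactions=())
        fit = fit_model(spec, df, seed=1, n_chains=2, n_iter=300, n_warmup=150, standardize=False)
        assert fit.pi_draws.mean() > 0.98

    def test_prior_only_slope_sd_is_one(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame(
            {
                "daily_distance_km": rng.uniform(1, 10, n),
                "refuge_dim1": rng.standard_normal(n),
                "individual_id": rng.choice(["a", "b", "c"], n),
                "grid_cell_id": rng.choice(["c1", "c2"], n),
                "track_date": "2010-06-01",
            }
        )
        spec = ModelSpec(response="daily_distance", fixed_terms=("refuge_dim1",), interactions=())
        fit = fit_model(spec, df, seed=2, n_chains=2, n_iter=1600, n_warmup=800, standardize=False, prior_only=True)
        d = fit.fixed_effect_draws()["refuge_dim1"]
        assert d.std() == pytest.approx(1.0, abs=0.15)
        assert abs(d.mean()) < 0.2

    def test_nonfinite_response_rejected(self):
        df = pd.DataFrame(
            {
                "daily_distance_km": [1.0, np.nan],
                "refuge_dim1": [0.0, 1.0],
                "individual_id": ["a", "a"],
                "grid_cell_id": ["c", "c"],
                "track_date": "2010-06-01",
            }
        )
        spec = ModelSpec(response="daily_distance", fixed_terms=("refuge_dim1",), interactions=())
        with pytest.raises(ValueError, match="non-finite"):
            fit_model(spec, df, n_chains=1, n_iter=20, n_warmup=10)

    def test_mixed_model_cross_check_against_reml(self):
        """Posterior means agree with a restricted-ML linear mixed model fit
        (statsmodels MixedLM) on the same single-random-effect data."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        n, n_ind = 600, 12
        ind = rng.integers(0, n_ind, n)
        a = rng.normal(0, 0.5, n_ind)
        x = rng.standard_normal(n)
        y = 2.0 + 0.6 * x + a[ind] + rng.normal(0, 0.4, n)
        df = pd.DataFrame(
            {
                "daily_distance_km": y**2,
                "refuge_dim1": x,
                "individual_id": [f"w{i}" for i in ind],
                "grid_cell_id": "c0",
                "track_date": "2010-06-01",
            }
        )
        spec = ModelSpec(response="daily_distance", fixed_terms=("refuge_dim1",), interactions=())
        fit = fit_model(spec, df, seed=6, n_chains=2, n_iter=1000, n_warmup=500, standardize=False)
        summ = fit.summary()
        ml = smf.mixedlm("np.sqrt(daily_distance_km) ~ refuge_dim1", df, groups=df["individual_id"]).fit()
        assert summ.loc["refuge_dim1", "mean"] == pytest.approx(ml.params["refuge_dim1"], abs=0.05)
        assert summ.loc["intercept", "mean"] == pytest.approx(ml.params["Intercept"], abs=0.3)
        assert summ.loc["sigma_resid", "mean"] == pytest.approx(np.sqrt(ml.scale), abs=0.05)


class TestPosteriorPredict:
    def test_predictions_correlate_with_observations(self, gauss_fit, gauss_records):
        rec, _ = gauss_records
        pred = posterior_predict(gauss_fit, rec)
        obs = rec["daily_distance_km"].to_numpy()
        assert np.corrcoef(obs, pred)[0, 1] ** 2 > 0.2

    def test_full_override_collapses_to_intercept_plus_randoms(self, gauss_fit, gauss_records):
        rec, _ = gauss_records
        overrides = {}
        for term in gauss_fit.meta.fixed_terms:
            overrides[term] = 0.0 if term in gauss_fit.meta.cont_means else CATEGORICAL_LEVELS[term][0]
        overrides.update(individual_id="__new__", grid_cell_id="__new__")
        pred = posterior_predict(gauss_fit, rec, overrides=overrides, scale="sqrt")
        assert np.ptp(pred) < 1e-9  # identical across records

    def test_monotone_in_positive_slope_predictor(self, gauss_fit, gauss_records):
        rec, _ = gauss_records
        d = gauss_fit.fixed_effect_draws()["refuge_dim1"]
        assert np.mean(d > 0) > 0.9  # simulated +0.3
        lo = posterior_predict(gauss_fit, rec, overrides={"refuge_dim1": -1.0})
        hi = posterior_predict(gauss_fit, rec, overrides={"refuge_dim1": 1.0})
        assert hi.mean() > lo.mean()

    def test_unknown_override_term_rejected(self, gauss_fit, gauss_records):
        rec, _ = gauss_records
        with pytest.raises(KeyError):
            posterior_predict(gauss_fit, rec, overrides={"prey": 0.0})
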