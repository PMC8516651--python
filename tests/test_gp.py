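"""Statistical core: likelihood oracle, Laplace fit, composition identity."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.special import expit, kv, logit
from scipy.stats import binom, multivariate_normal, norm

from anemiamap.gp import (
    KnotLattice,
    ModelConfig,
    ModelInputs,
    _build_stage_data,
    _default_priors,
    _LaplaceModel,
    compose_marginals,
    fit_continuation_ratio,
    fit_stage,
)
from anemiamap.grids import GridSpec
from anemiamap.kronecker import ar1_correlation, compute_kappa


def _flat_inputs(n_rows=6, n_cols=6, years=(2014, 2015, 2016), n_countries=1):
    grid = GridSpec(0.0, 0.0, 1.0, n_rows, n_cols, years)
    country = np.zeros((n_rows, n_cols), dtype=int)
    if n_countries > 1:
        country[:, n_cols // 2 :] = 1
    return ModelInputs(grid=grid, covariates={}, country_map=country)


def _random_obs(rng, inputs, n_obs=40, p=0.3, N=400):
    grid = inputs.grid
    lon = rng.uniform(0, grid.n_cols - 1, n_obs)
    lat = rng.uniform(0, grid.n_rows - 1, n_obs)
    year = rng.choice(grid.years, n_obs)
    y = rng.binomial(N, p, n_obs)
    return pd.DataFrame(
        {
            "cluster_id": [f"c{i}" for i in range(n_obs)],
            "lon": lon, "lat": lat, "year": year, "weight": 1.0,
            "N": N, "anemic": y, "mild": 0, "moderate": 0, "severe": 0,
        }
    ).assign(mild=lambda d: d["anemic"])


class TestKnotLattice:
    def test_partition_of_unity_and_exactness(self, rng):
        grid = GridSpec(0.0, 0.0, 0.5, 10, 10, (2015, 2016))
        lat = KnotLattice(grid, spacing_cells=3)
        lon_pts = rng.uniform(0, 4.5, 30)
        lat_pts = rng.uniform(0, 4.5, 30)
        years = rng.integers(0, 2, 30)
        A = lat.projection(lon_pts, lat_pts, years, 2)
        np.testing.assert_allclose(A.sum(axis=1), 1.0)
        # at a knot the projection is an indicator
        A0 = lat.projection([lat.lons[1]], [lat.lats[2]], [1], 2)
        assert A0.max() == pytest.approx(1.0)
        assert (A0 > 0).sum() == 1


class TestJointLogPosterior:
    def test_matches_bruteforce_oracle(self, rng):
        inputs = _flat_inputs(n_countries=2)
        obs = _random_obs(rng, inputs, n_obs=15, N=50)
        config = ModelConfig(variant="raw_gp", knot_spacing_cells=3,
                             use_country_re=True)
        data = _build_stage_data(obs, inputs, 1, config)
        lattice = KnotLattice(inputs.grid, 3)
        model = _LaplaceModel(data, lattice, inputs.grid.n_years, 2, config,
                              _default_priors(inputs.grid))
        theta = np.array([np.log(0.4), np.log(2.5), np.arctanh(0.6),
                          np.log(0.1), np.log(0.05)])
        u = 0.1 * rng.standard_normal(model.n_latent)

        value = model.joint_log_posterior(u, theta)

        # brute force: dense latent prior + weighted binomial + hyperpriors
        omega2, delta, rho = 0.4, 2.5, 0.6
        gamma2, sigma2 = 0.1, 0.05
        kappa = compute_kappa(2.0, delta)
        D = np.linalg.norm(
            lattice.knots[:, None, :] - lattice.knots[None, :, :], axis=-1
        )
        kd = kappa * D
        with np.errstate(invalid="ignore"):
            M = (kd**2) * kv(2, kd) / 2.0
        M[np.isnan(M)] = 1.0
        M = omega2 * M + np.eye(len(M)) * 1e-10 * omega2
        S = np.kron(M, ar1_correlation(inputs.grid.n_years, rho))
        blocks = [
            np.eye(model.p) * config.fixed_effect_prior_sd**2,
            S,
            np.eye(2) * gamma2,
            np.eye(model.n_obs) * sigma2,
        ]
        cov = np.zeros((model.n_latent, model.n_latent))
        i = 0
        for b in blocks:
            cov[i : i + len(b), i : i + len(b)] = b
            i += len(b)
        lp_latent = multivariate_normal(np.zeros(model.n_latent), cov).logpdf(u)
        eta = model.A @ u + data.offset
        lp_y = float(np.sum(data.w * binom.logpmf(data.y, data.n, expit(eta))))
        priors = _default_priors(inputs.grid)
        lp_theta = sum(
            norm.logpdf(t, *priors[name])
            for name, t in zip(model.hyper_names, theta)
        )
        assert value == pytest.approx(lp_latent + lp_y + lp_theta, abs=1e-6)


class TestFitStage:
    def test_fixed_effect_only_limit(self, rng):
        # near-zero process/nugget variance and large N: the intercept
        # posterior concentrates at the generating logit(0.3)
        inputs = _flat_inputs()
        obs = _random_obs(rng, inputs, n_obs=60, p=0.3, N=500)
        config = ModelConfig(variant="raw", n_draws=300, n_hyper_draws=5)
        fit = fit_stage(obs, inputs, 1, config, seed=0)
        beta0 = fit.beta_draws()["beta0"]
        assert beta0.mean() == pytest.approx(logit(0.3), abs=0.05)
        # single country: no country random effect in the model
        assert "log_gamma2" not in fit.hyper_names

    def test_variant_controls_structure(self, rng):
        inputs = _flat_inputs(n_countries=2)
        obs = _random_obs(rng, inputs, n_obs=30, N=100)
        fit = fit_stage(obs, inputs, 1,
                        ModelConfig(variant="raw", n_draws=50, n_hyper_draws=2),
                        seed=1)
        assert "log_omega2" not in fit.hyper_names
        with pytest.raises(ValueError):
            ModelConfig(variant="bogus")

    def test_stacked_weights_sum_to_one(self, rng):
        inputs = _flat_inputs()
        obs = _random_obs(rng, inputs, n_obs=30, N=100)
        from anemiamap.stackers import StackerPredictions

        grid = inputs.grid
        s_obs = rng.normal(0, 0.5, size=(30, 3))
        s_grid = rng.normal(
            0, 0.5, size=(3, grid.n_years, grid.n_rows, grid.n_cols)
        )
        inputs.stackers = {1: StackerPredictions(obs=s_obs, grid=s_grid)}
        fit = fit_stage(obs, inputs, 1,
                        ModelConfig(variant="stack", n_draws=100, n_hyper_draws=3),
                        seed=2)
        betas = fit.beta_draws()
        total = betas["beta1"] + betas["beta2"] + betas["beta3"]
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestComposeMarginals:
    def test_worked_example(self):
        mild, moderate, severe = compose_marginals(0.4, 0.5, 0.1)
        assert mild == pytest.approx(0.20)
        assert moderate == pytest.approx(0.18)
        assert severe == pytest.approx(0.02)

    def test_zero_prevalence(self):
        assert compose_marginals(0.0, 0.7, 0.9) == (0.0, 0.0, 0.0)

    def test_identity_random_inputs(self, rng):
        p, pm, ps = rng.uniform(0, 1, (3, 500))
        mild, moderate, severe = compose_marginals(p, pm, ps)
        np.testing.assert_allclose(mild + moderate + severe, p, atol=1e-15)
        assert np.all((mild >= 0) & (severe >= 0) & (moderate >= -1e-15))


class TestContinuationRatio:
    def test_inconsistent_counts_rejected(self, rng):
        inputs = _flat_inputs()
        obs = _random_obs(rng, inputs, n_obs=10, N=50)
        obs.loc[0, "mild"] = obs.loc[0, "anemic"] + 1
        with pytest.raises(ValueError):
            fit_continuation_ratio(obs, inputs, ModelConfig(variant="raw"), 0)

    def test_zero_anemia_gives_stage1_only(self, rng):
        inputs = _flat_inputs()
        obs = _random_obs(rng, inputs, n_obs=15, N=40)
        obs[["anemic", "mild", "moderate", "severe"]] = 0
        cr = fit_continuation_ratio(
            obs, inputs, ModelConfig(variant="raw", n_draws=30, n_hyper_draws=2), 0
        )
        assert cr.stage1_only and set(cr.stages) == {1}
        ds = cr.prevalence_draws(inputs)
        assert set(ds.data_vars) == {"overall"}

    def test_pipeline_draws_structure(self, small_config, small_ws):
        ds = xr.open_dataset(small_ws / "draws.nc", engine="scipy").load()
        ds.close()
        assert ds.sizes["draw"] == small_config.model.n_draws
        assert set(ds.data_vars) == {"overall", "mild", "moderate", "severe"}
        total = ds["mild"] + ds["moderate"] + ds["severe"]
        np.testing.assert_allclose(total.values, ds["overall"].values, atol=1e-12)

    def test_grid_posterior_mean_tracks_truth(self, default_ws):
        from anemiamap.pipeline import scenario_from_netcdf

        ds = xr.open_dataset(default_ws / "draws.nc", engine="scipy").load()
        ds.close()
        scenario = scenario_from_netcdf(default_ws / "scenario.nc")
        est = ds["overall"].mean("draw").values
        truth = scenario.stage_truths["anemic"]
        assert np.corrcoef(est.ravel(), truth.ravel())[0, 1] > 0.8
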