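"""Generator correctness: field covariance, severity structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from anemiamap.grids import GridSpec
from anemiamap.kronecker import GPHyperparameters, ar1_correlation, matern_correlation
from anemiamap.synthetic import (
    build_default_scenario,
    generate_national_series,
    national_truth,
    simulate_areal_observations,
    simulate_cluster_microdata,
    simulate_space_time_field,
)

PARAMS = GPHyperparameters(
    omega2=1.0, delta=2.0, rho=0.5, gamma2_country=0.1, sigma2_nugget=0.1
)
TINY_GRID = GridSpec(0.0, 0.0, 1.0, 3, 3, (2000, 2001))


class TestSpaceTimeField:
    def test_zero_variance_limit(self):
        p = GPHyperparameters(
            omega2=1e-14, delta=2.0, rho=0.5, gamma2_country=0.1, sigma2_nugget=0.1
        )
        field = simulate_space_time_field(TINY_GRID, p, seed=0)
        assert np.all(field == 0.0)

    def test_seed_determinism(self):
        a = simulate_space_time_field(TINY_GRID, PARAMS, seed=9)
        b = simulate_space_time_field(TINY_GRID, PARAMS, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_lag1_temporal_correlation(self):
        # 2,000 replicate fields: empirical lag-1 correlation ~= rho
        fields = simulate_space_time_field(TINY_GRID, PARAMS, seed=1, size=2000)
        x = fields[:, 0, 1, 1]
        y = fields[:, 1, 1, 1]
        corr = np.corrcoef(x, y)[0, 1]
        assert corr == pytest.approx(PARAMS.rho, abs=0.05)

    def test_covariance_matches_analytic_kernel(self):
        # sample covariance at two fixed cells vs the analytic kernel entry,
        # within 3 Monte-Carlo standard errors
        n_rep = 5000
        fields = simulate_space_time_field(TINY_GRID, PARAMS, seed=2, size=n_rep)
        for (r1, c1, t1), (r2, c2, t2) in [
            ((0, 0, 0), (2, 1, 0)),
            ((1, 1, 0), (1, 1, 1)),
            ((0, 2, 1), (2, 0, 0)),
        ]:
            a = fields[:, t1, r1, c1]
            b = fields[:, t2, r2, c2]
            d = np.hypot(r1 - r2, c1 - c2) * TINY_GRID.cell_size
            expected = (
                PARAMS.omega2
                * matern_correlation(d, PARAMS.kappa)
                * ar1_correlation(2, PARAMS.rho)[t1, t2]
            )
            sample_cov = np.mean(a * b)
            # var of the product estimator for a bivariate normal pair
            mc_se = np.sqrt(
                (PARAMS.omega2**2 + expected**2) / n_rep
            )
            assert abs(sample_cov - expected) < 3 * mc_se


class TestScenario:
    def test_full_determinism(self):
        a = build_default_scenario(seed=3)
        b = build_default_scenario(seed=3)
        np.testing.assert_array_equal(
            a.stage_truths["anemic"], b.stage_truths["anemic"]
        )
        np.testing.assert_array_equal(a.population, b.population)
        ma = simulate_cluster_microdata(a, 20, 10, seed=4)
        mb = simulate_cluster_microdata(b, 20, 10, seed=4)
        pd.testing.assert_frame_equal(ma, mb)

    def test_severity_identity(self, scenario):
        total = (
            scenario.marginal_truth("mild")
            + scenario.marginal_truth("moderate")
            + scenario.marginal_truth("severe")
        )
        np.testing.assert_allclose(total, scenario.marginal_truth("overall"),
                                   atol=1e-12)

    def test_probability_surfaces_in_unit_interval(self, scenario):
        for surf in scenario.stage_truths.values():
            assert surf.min() >= 0 and surf.max() <= 1


class TestClusterMicrodata:
    def test_bookkeeping(self, scenario):
        micro = simulate_cluster_microdata(scenario, 50, 30, seed=8)
        assert micro["cluster_id"].nunique() == 50
        assert 1000 < len(micro) < 2200  # ~1,500 women
        assert scenario.grid.contains(micro["lon"], micro["lat"]).all()
        assert micro["age"].between(15, 49).all()

    def test_zero_prevalence_truth(self, scenario):
        import dataclasses

        zero = dataclasses.replace(
            scenario,
            stage_truths={k: np.zeros_like(v) for k, v in scenario.stage_truths.items()},
        )
        micro = simulate_cluster_microdata(zero, 20, 15, seed=0)
        assert (micro["true_category"] == "non_anemic").all()

    def test_degenerate_severe_truth(self, scenario):
        import dataclasses

        ones = dataclasses.replace(
            scenario,
            stage_truths={
                "anemic": np.ones_like(scenario.stage_truths["anemic"]),
                "mild_given_anemic": np.zeros_like(scenario.stage_truths["anemic"]),
                "severe_given_modsev": np.ones_like(scenario.stage_truths["anemic"]),
            },
        )
        micro = simulate_cluster_microdata(ones, 20, 15, seed=0)
        assert (micro["true_category"] == "severe").all()

    def test_empty_population_rejected(self, scenario):
        import dataclasses

        empty = dataclasses.replace(
            scenario, population=np.zeros_like(scenario.population)
        )
        with pytest.raises(ValueError):
            simulate_cluster_microdata(empty, 5, 5, seed=0)


class TestArealObservations:
    def test_record_count_and_consistency(self, scenario):
        obs, polys = simulate_areal_observations(scenario, None, 4, seed=1)
        assert len(obs) == 4 == len(polys)
        assert (obs["mild"] + obs["moderate"] + obs["severe"] == obs["anemic"]).all()
        assert (obs["anemic"] <= obs["N"]).all()

    def test_single_cell_polygon_binomial(self, scenario):
        from shapely.geometry import box

        grid = scenario.grid
        r, c = 5, 5
        half = grid.cell_size / 2
        poly = box(grid.lons[c] - half, grid.lats[r] - half,
                   grid.lons[c] + half, grid.lats[r] + half)
        obs, _ = simulate_areal_observations(
            scenario, {0: poly}, seed=3, n_per_polygon=20000
        )
        year_idx = grid.year_index(obs.loc[0, "year"])
        p = scenario.stage_truths["anemic"][year_idx, r, c]
        phat = obs.loc[0, "anemic"] / obs.loc[0, "N"]
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(phat - p) < 4 * se

    def test_uniform_truth_sampling_error(self, scenario):
        import dataclasses

        flat = dataclasses.replace(
            scenario,
            stage_truths={
                "anemic": np.full_like(scenario.stage_truths["anemic"], 0.3),
                "mild_given_anemic": np.full_like(scenario.stage_truths["anemic"], 0.5),
                "severe_given_modsev": np.full_like(scenario.stage_truths["anemic"], 0.1),
            },
        )
        obs, _ = simulate_areal_observations(flat, None, 3, seed=4, n_per_polygon=10000)
        props = obs["anemic"] / obs["N"]
        assert np.all(np.abs(props - 0.3) < 0.015)

    def test_zero_population_polygon_skipped(self, scenario):
        import dataclasses

        from shapely.geometry import box

        nopop = dataclasses.replace(
            scenario, population=np.zeros_like(scenario.population)
        )
        poly = box(*([scenario.grid.origin_lon - 0.2, scenario.grid.origin_lat - 0.2,
                      scenario.grid.origin_lon + 0.7, scenario.grid.origin_lat + 0.7]))
        obs, kept = simulate_areal_observations(nopop, {0: poly}, seed=0)
        assert obs.empty and not kept


class TestNationalSeries:
    def test_identity_bias(self, scenario):
        series = generate_national_series(scenario, bias_factor=1.0,
                                          years=scenario.grid.years)
        truth = national_truth(scenario)
        pd.testing.assert_frame_equal(series, truth)

    def test_multiplicative_bias(self, scenario):
        base = generate_national_series(scenario, 1.0)
        biased = generate_national_series(scenario, 1.2)
        np.testing.assert_allclose(biased["value"], 1.2 * base["value"])

    def test_default_years_exclude_last(self, scenario):
        series = generate_national_series(scenario, 1.1)
        assert series["year"].max() == scenario.grid.years[-2]
        assert set(series["country"]) == set(range(scenario.n_countries))
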