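"""Stage orchestration: simulate → preprocess → stack → fit → postest →
rake → project → validate.

Each stage reads its prerequisites from a workspace directory, writes named
artifacts plus a manifest (config hash, seed, input hashes), and is skipped
on re-run when nothing changed.  All randomness derives from the single
pipeline seed via per-stage ``SeedSequence`` spawns, so a full run is
reproducible bit-for-bit at the level of its summary CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import aggregation, raking, trends, validation
from .config import PipelineConfig
from .gp import ModelConfig, ModelInputs, fit_continuation_ratio, fit_stage
from .grids import GridSpec, write_raster
from .hemoglobin import collapse_to_clusters, resample_polygon
from .kronecker import GPHyperparameters
from .stackers import LEARNERS, StackerPredictions, fit_stackers
from .synthetic import (
    TruthScenario,
    build_default_scenario,
    generate_national_series,
    make_admin_polygons,
    simulate_areal_observations,
    simulate_cluster_microdata,
)

logger = logging.getLogger(__name__)

__all__ = ["STAGES", "PipelineError", "run_stage", "run_all"]

STAGES = ["simulate", "preprocess", "stack", "fit", "postest", "rake",
          "project", "validate"]
_PREREQS = {
    "simulate": [],
    "preprocess": ["microdata.csv", "areal.csv", "polygons.geojson", "scenario.nc"],
    "stack": ["clusters.csv", "scenario.nc"],
    "fit": ["clusters.csv", "stacker_obs.csv", "stacker_grid.nc", "scenario.nc"],
    "postest": ["draws.nc", "scenario.nc"],
    "rake": ["draws.nc", "national_series.csv", "scenario.nc"],
    "project": ["aggregate_draws.nc"],
    "validate": ["clusters.csv", "stacker_obs.csv", "stacker_grid.nc", "scenario.nc"],
}
_PRODUCER = {
    "scenario.nc": "simulate", "microdata.csv": "simulate", "areal.csv": "simulate",
    "polygons.geojson": "simulate", "national_series.csv": "simulate",
    "clusters.csv": "preprocess", "stacker_obs.csv": "stack",
    "stacker_grid.nc": "stack", "draws.nc": "fit",
    "aggregate_draws.nc": "rake",
}


class PipelineError(RuntimeError):
    pass


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# scenario persistence
# ---------------------------------------------------------------------------

def scenario_to_netcdf(scenario: TruthScenario, path: Path) -> None:
    grid = scenario.grid
    data = {}
    for name, surf in scenario.stage_truths.items():
        data[f"truth_{name}"] = (("year", "row", "col"), surf)
    for name, cov in scenario.covariates.items():
        data[f"cov_{name}"] = (("row", "col"), cov)
    for name, arr in (
        ("population", scenario.population),
        ("elevation", scenario.elevation),
        ("country_map", scenario.country_map.astype(float)),
        ("admin1_map", scenario.admin1_map.astype(float)),
        ("admin2_map", scenario.admin2_map.astype(float)),
        ("barren", scenario.barren_mask.astype(float)),
    ):
        data[name] = (("row", "col"), arr)
    ds = xr.Dataset(
        data,
        coords={"year": list(grid.years), "row": np.arange(grid.n_rows),
                "col": np.arange(grid.n_cols)},
        attrs={
            "grid": json.dumps(grid.to_dict()),
            "beta0": list(scenario.beta0),
            "covariate_names": json.dumps(list(scenario.covariates)),
            "covariate_effects": json.dumps(scenario.covariate_effects),
            "gp_params": json.dumps(dataclasses.asdict(scenario.gp_params)),
            "country_effects": list(scenario.country_effects),
            "seed": scenario.seed,
            "adjustment": json.dumps(
                {
                    "elevation_bins": list(map(list, scenario.adjustment_tables.elevation_bins)),
                    "smoking_decrement": scenario.adjustment_tables.smoking_decrement,
                    "non_pregnant": list(scenario.thresholds.non_pregnant),
                    "pregnant": list(scenario.thresholds.pregnant),
                }
            ),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def scenario_from_netcdf(path: Path) -> TruthScenario:
    from .hemoglobin import AdjustmentTables, SeverityThresholds

    ds = xr.open_dataset(path, engine="scipy").load()
    ds.close()
    grid = GridSpec.from_dict(json.loads(ds.attrs["grid"]))
    adj = json.loads(ds.attrs["adjustment"])
    names = json.loads(ds.attrs["covariate_names"])
    return TruthScenario(
        grid=grid,
        beta0=tuple(np.atleast_1d(ds.attrs["beta0"]).tolist()),
        covariate_effects=json.loads(ds.attrs["covariate_effects"]),
        gp_params=GPHyperparameters(**json.loads(ds.attrs["gp_params"])),
        country_effects=np.atleast_1d(ds.attrs["country_effects"]),
        stage_truths={
            name.removeprefix("truth_"): ds[name].values
            for name in ds.data_vars
            if name.startswith("truth_")
        },
        covariates={n: ds[f"cov_{n}"].values for n in names},
        population=ds["population"].values,
        elevation=ds["elevation"].values,
        country_map=ds["country_map"].values.astype(int),
        admin1_map=ds["admin1_map"].values.astype(int),
        admin2_map=ds["admin2_map"].values.astype(int),
        barren_mask=ds["barren"].values.astype(bool),
        seed=int(ds.attrs["seed"]),
        adjustment_tables=AdjustmentTables(
            elevation_bins=tuple(map(tuple, adj["elevation_bins"])),
            smoking_decrement=adj["smoking_decrement"],
        ),
        thresholds=SeverityThresholds(
            non_pregnant=tuple(adj["non_pregnant"]), pregnant=tuple(adj["pregnant"])
        ),
    )


def _write_geojson(path: Path, polygons: dict[int, object]) -> None:
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {"id": int(pid)},
         "geometry": mapping(poly)}
        for pid, poly in sorted(polygons.items())
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def _read_geojson(path: Path) -> dict[int, object]:
    from shapely.geometry import shape

    gj = json.loads(path.read_text())
    return {
        int(f["properties"]["id"]): shape(f["geometry"]) for f in gj["features"]
    }


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest_path(ws: Path, stage: str) -> Path:
    return ws / f"manifest_{stage}.json"


def _check_prereqs(ws: Path, stage: str) -> dict[str, str]:
    hashes = {}
    for name in _PREREQS[stage]:
        p = ws / name
        if not p.exists():
            raise PipelineError(
                f"stage '{stage}' is missing input '{name}'; "
                f"run stage '{_PRODUCER[name]}' first"
            )
        hashes[name] = _file_hash(p)
    return hashes


def _stage_is_current(ws: Path, stage: str, config: PipelineConfig,
                      input_hashes: dict[str, str]) -> bool:
    mpath = _manifest_path(ws, stage)
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    return (
        manifest.get("config_hash") == config.config_hash()
        and manifest.get("inputs") == input_hashes
        and all((ws / o).exists() for o in manifest.get("outputs", []))
    )


def _write_stage_manifest(ws: Path, stage: str, config: PipelineConfig,
                          input_hashes: dict[str, str], outputs: list[str]) -> None:
    _manifest_path(ws, stage).write_text(
        json.dumps(
            {
                "stage": stage,
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "inputs": input_hashes,
                "outputs": outputs,
            },
            indent=1,
        )
    )


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _scenario_from_config(config: PipelineConfig) -> TruthScenario:
    sc = config.scenario
    scenario = build_default_scenario(
        seed=config.seed,
        n_rows=sc.n_rows,
        n_cols=sc.n_cols,
        cell_size=sc.cell_size,
        origin_lon=sc.origin_lon,
        origin_lat=sc.origin_lat,
        years=tuple(sc.years),
        n_countries=sc.n_countries,
        beta0=tuple(sc.beta0),
        covariate_effects=dict(sc.covariate_effects),
        gp_params=sc.gp_params(),
    )
    scenario.adjustment_tables = config.adjustment.tables()
    scenario.thresholds = config.adjustment.thresholds()
    return scenario


def _stage_simulate(config: PipelineConfig, ws: Path) -> list[str]:
    sc = config.scenario
    seed = _stage_seed(config, "simulate")
    scenario = _scenario_from_config(config)
    micro = simulate_cluster_microdata(
        scenario, sc.n_clusters, sc.mean_cluster_size, seed=seed,
        pregnant_rate=sc.pregnant_rate, smoker_rate=sc.smoker_rate,
    )
    areal, polygons = simulate_areal_observations(
        scenario, None, sc.n_polygons, seed=seed + 1, n_per_polygon=sc.areal_n
    )
    series = generate_national_series(scenario, bias_factor=sc.national_bias)

    scenario_to_netcdf(scenario, ws / "scenario.nc")
    micro.to_csv(ws / "microdata.csv", index=False)
    areal.to_csv(ws / "areal.csv", index=False)
    series.to_csv(ws / "national_series.csv", index=False)
    _write_geojson(ws / "polygons.geojson", polygons)
    for level, amap in (("admin0", scenario.country_map),
                        ("admin1", scenario.admin1_map),
                        ("admin2", scenario.admin2_map)):
        _write_geojson(ws / f"{level}.geojson",
                       make_admin_polygons(scenario.grid, amap))
    rasters = ws / "rasters"
    rasters.mkdir(exist_ok=True)
    write_raster(rasters / "population.tif", scenario.population, scenario.grid)
    write_raster(rasters / "elevation.tif", scenario.elevation, scenario.grid)
    write_raster(rasters / "country_map.tif", scenario.country_map, scenario.grid)
    for name, cov in scenario.covariates.items():
        write_raster(rasters / f"{name}.tif", cov, scenario.grid)
    return ["scenario.nc", "microdata.csv", "areal.csv", "national_series.csv",
            "polygons.geojson", "admin0.geojson", "admin1.geojson", "admin2.geojson"]


def _stage_preprocess(config: PipelineConfig, ws: Path) -> list[str]:
    scenario = scenario_from_netcdf(ws / "scenario.nc")
    micro = pd.read_csv(ws / "microdata.csv")
    clusters = collapse_to_clusters(
        micro, scenario.adjustment_tables, scenario.thresholds
    )
    areal = pd.read_csv(ws / "areal.csv")
    polygons = _read_geojson(ws / "polygons.geojson")
    rng = np.random.default_rng(_stage_seed(config, "preprocess"))
    parts = [clusters]
    for _, row in areal.iterrows():
        parts.append(
            resample_polygon(
                row, polygons[int(row["polygon_id"])], scenario.population,
                scenario.grid, config.preprocess.rule(), rng,
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(ws / "clusters.csv", index=False)
    return ["clusters.csv"]


def _grid_covariate_stack(scenario: TruthScenario) -> np.ndarray:
    grid = scenario.grid
    layers = [
        np.tile(scenario.covariates[name], (grid.n_years, 1, 1))
        for name in scenario.covariates
    ]
    return np.stack(layers, axis=-1)  # (years, rows, cols, p)


def _obs_covariates(scenario: TruthScenario, clusters: pd.DataFrame) -> np.ndarray:
    row, col = scenario.grid.cell_index(clusters["lon"], clusters["lat"])
    return np.column_stack(
        [scenario.covariates[name][row, col] for name in scenario.covariates]
    )


def _stage_stack(config: PipelineConfig, ws: Path) -> list[str]:
    scenario = scenario_from_netcdf(ws / "scenario.nc")
    clusters = pd.read_csv(ws / "clusters.csv")
    obs_cov = _obs_covariates(scenario, clusters)
    grid_cov = _grid_covariate_stack(scenario)
    seed = _stage_seed(config, "stack")

    obs_out = {}
    grid_vars = {}
    for stage in (1, 2, 3):
        preds = fit_stackers(
            clusters, obs_cov, grid_cov, stage,
            cv_folds=config.stacker.cv_folds, seed=seed + stage,
            config=config.stacker.learner_config(),
        )
        for j, learner in enumerate(LEARNERS):
            obs_out[f"s{stage}_{learner}"] = preds.obs[:, j]
        grid_vars[f"stage{stage}"] = (("learner", "year", "row", "col"), preds.grid)
    pd.DataFrame(obs_out).to_csv(ws / "stacker_obs.csv", index=False)
    xr.Dataset(
        grid_vars,
        coords={"learner": list(LEARNERS), "year": list(scenario.grid.years),
                "row": np.arange(scenario.grid.n_rows),
                "col": np.arange(scenario.grid.n_cols)},
    ).to_netcdf(ws / "stacker_grid.nc", engine="scipy")
    return ["stacker_obs.csv", "stacker_grid.nc"]


def _load_model_inputs(ws: Path, scenario: TruthScenario) -> ModelInputs:
    obs = pd.read_csv(ws / "stacker_obs.csv")
    grid_ds = xr.open_dataset(ws / "stacker_grid.nc", engine="scipy").load()
    grid_ds.close()
    stackers = {
        stage: StackerPredictions(
            obs=obs[[f"s{stage}_{l}" for l in LEARNERS]].to_numpy(),
            grid=grid_ds[f"stage{stage}"].values,
        )
        for stage in (1, 2, 3)
    }
    return ModelInputs(
        grid=scenario.grid,
        covariates=scenario.covariates,
        country_map=scenario.country_map,
        stackers=stackers,
    )


def _stage_fit(config: PipelineConfig, ws: Path) -> list[str]:
    scenario = scenario_from_netcdf(ws / "scenario.nc")
    clusters = pd.read_csv(ws / "clusters.csv")
    inputs = _load_model_inputs(ws, scenario)
    model_config = config.model.model_config_obj()
    cr = fit_continuation_ratio(
        clusters, inputs, model_config, seed=_stage_seed(config, "fit")
    )
    draws = cr.prevalence_draws(inputs)
    draws.to_netcdf(ws / "draws.nc", engine="scipy")

    hyper_rows = []
    weight_rows = []
    for stage, fit in cr.stages.items():
        for name in fit.params_map:
            lo, hi = fit.hyper_interval(name)
            hyper_rows.append(
                {"stage": stage, "parameter": name,
                 "map": fit.params_map[name], "lower95": lo, "upper95": hi}
            )
        betas = fit.beta_draws()
        for col in betas:
            weight_rows.append(
                {"stage": stage, "coefficient": col,
                 "mean": float(betas[col].mean()),
                 "lower95": float(betas[col].quantile(0.025)),
                 "upper95": float(betas[col].quantile(0.975))}
            )
    pd.DataFrame(hyper_rows).to_csv(ws / "hyperparams.csv", index=False)
    pd.DataFrame(weight_rows).to_csv(ws / "stacker_weights.csv", index=False)
    return ["draws.nc", "hyperparams.csv", "stacker_weights.csv"]


def _admin_maps(scenario: TruthScenario) -> dict[int, np.ndarray]:
    return {0: scenario.country_map, 1: scenario.admin1_map, 2: scenario.admin2_map}


def _stage_postest(config: PipelineConfig, ws: Path) -> list[str]:
    scenario = scenario_from_netcdf(ws / "scenario.nc")
    draws = xr.open_dataset(ws / "draws.nc", engine="scipy").load()
    draws.close()
    keep = aggregation.apply_mask(
        scenario.population, scenario.barren_mask, scenario.grid,
        config.postest.mask_threshold_per_km2,
    )
    frames = []
    for level, amap in _admin_maps(scenario).items():
        agg = aggregation.aggregate_to_admin(draws, scenario.population, amap, keep)
        frames.append(aggregation.summarize_aggregates(agg, level))
    pd.concat(frames, ignore_index=True).to_csv(
        ws / "admin_prevalence_unraked.csv", index=False
    )
    return ["admin_prevalence_unraked.csv"]


def _stage_rake(config: PipelineConfig, ws: Path) -> list[str]:
    scenario = scenario_from_netcdf(ws / "scenario.nc")
    draws = xr.open_dataset(ws / "draws.nc", engine="scipy").load()
    draws.close()
    series = pd.read_csv(ws / "national_series.csv")
    keep = aggregation.apply_mask(
        scenario.population, scenario.barren_mask, scenario.grid,
        config.postest.mask_threshold_per_km2,
    )
    years = np.array(scenario.grid.years)

    if config.raking.enabled:
        national = aggregation.aggregate_to_admin(
            draws[["overall"]], scenario.population, scenario.country_map, keep
        )["overall"]
        factors, avail_years, countries = raking.compute_raking_factors(national, series)
        full, provenance = raking.interpolate_factors(factors, avail_years, years)
        raked = raking.apply_raking(draws, full, countries, scenario.country_map)
        raking.raking_table(full, countries, years, provenance).to_csv(
            ws / "raking_table.csv", index=False
        )
    else:
        raked = draws
        pd.DataFrame(
            columns=["country", "year", "indicator", "factor", "provenance"]
        ).to_csv(ws / "raking_table.csv", index=False)
    raked.to_netcdf(ws / "raked_draws.nc", engine="scipy")

    dw = config.postest.disability_weights()
    prev_frames, count_frames, yld_frames = [], [], []
    agg_draw_vars = {}
    class_rows = []
    ineq_admin2 = None
    national_means = None
    for level, amap in _admin_maps(scenario).items():
        agg = aggregation.aggregate_to_admin(raked, scenario.population, amap, keep)
        wra = aggregation.unit_population(
            scenario.population, amap, keep, config.postest.wra_fraction
        )
        counts = aggregation.compute_counts(agg, wra)
        ylds = aggregation.compute_ylds(counts, dw)
        prev_frames.append(aggregation.summarize_aggregates(agg, level))
        count_frames.append(aggregation.summarize_aggregates(counts, level))
        yld_frames.append(aggregation.summarize_aggregates(ylds, level))
        for var in agg.data_vars:
            agg_draw_vars[f"{var}_admin{level}"] = agg[var].rename(
                {"unit": f"unit{level}"}
            )
        means = agg["overall"].mean("draw")
        for u in agg["unit"].values:
            for y in agg["year"].values:
                class_rows.append(
                    {"level": level, "unit": int(u), "year": int(y),
                     "mean": float(means.sel(unit=u, year=y)),
                     "class": aggregation.classify_public_health_problem(
                         float(means.sel(unit=u, year=y))
                     ).item()}
                )
        if level == 2:
            last = means.sel(year=years[-1])
            country_of_unit = {
                int(u): int(scenario.country_map[scenario.admin2_map == u][0])
                for u in agg["unit"].values
            }
            ineq_admin2 = pd.DataFrame(
                {
                    "country": [country_of_unit[int(u)] for u in agg["unit"].values],
                    "unit": [int(u) for u in agg["unit"].values],
                    "mean": [float(last.sel(unit=u)) for u in agg["unit"].values],
                }
            )
        if level == 0:
            last = means.sel(year=years[-1])
            national_means = pd.DataFrame(
                {
                    "country": [int(u) for u in agg["unit"].values],
                    "mean": [float(last.sel(unit=u)) for u in agg["unit"].values],
                }
            )

    pd.concat(prev_frames, ignore_index=True).to_csv(ws / "admin_prevalence.csv", index=False)
    pd.concat(count_frames, ignore_index=True).to_csv(ws / "admin_counts.csv", index=False)
    pd.concat(yld_frames, ignore_index=True).to_csv(ws / "admin_ylds.csv", index=False)
    pd.DataFrame(class_rows).to_csv(ws / "public_health_class.csv", index=False)
    aggregation.inequality_summaries(ineq_admin2, national_means).to_csv(
        ws / "inequality.csv", index=False
    )
    xr.Dataset(agg_draw_vars).to_netcdf(ws / "aggregate_draws.nc", engine="scipy")
    return ["raking_table.csv", "raked_draws.nc", "admin_prevalence.csv",
            "admin_counts.csv", "admin_ylds.csv", "public_health_class.csv",
            "inequality.csv", "aggregate_draws.nc"]


def _stage_project(config: PipelineConfig, ws: Path) -> list[str]:
    agg = xr.open_dataset(ws / "aggregate_draws.nc", engine="scipy").load()
    agg.close()
    tc = config.trends
    years = agg["year"].values.astype(int)
    if tc.baseline_year in years:
        baseline_year = tc.baseline_year
    else:
        baseline_year = int(years[0])
        logger.info(
            "baseline year %d outside estimation years; using %d",
            tc.baseline_year, baseline_year,
        )
    weights = trends.aroc_weights(years[1:], tc.aroc_gamma, tc.origin_year)

    rows = []
    for level in (0, 1, 2):
        da = agg[f"overall_admin{level}"]  # (draw, year, unit)
        for u in da[f"unit{level}"].values:
            series = da.sel({f"unit{level}": u}).transpose("draw", "year").values
            pw = trends.pairwise_aroc(series, tc.use_printed_formula)
            aroc = trends.weighted_aroc(pw, weights)  # per draw
            p_last = series[:, -1]
            base = series[:, list(years).index(baseline_year)]
            row = {
                "level": level,
                "unit": int(u),
                "baseline_year": baseline_year,
                "aroc_mean": float(aroc.mean()),
                "aroc_lower95": float(np.quantile(aroc, 0.025)),
                "aroc_upper95": float(np.quantile(aroc, 0.975)),
            }
            for target in tc.target_years:
                k = int(target) - int(years[-1])
                proj = trends.project(p_last, aroc, k)
                prob = trends.gnt_probability(proj, base)
                row[f"proj_{target}_mean"] = float(proj.mean())
                row[f"proj_{target}_point"] = float(
                    trends.project(p_last.mean(), aroc.mean(), k)
                )
                row[f"proj_{target}_lower95"] = float(np.quantile(proj, 0.025))
                row[f"proj_{target}_upper95"] = float(np.quantile(proj, 0.975))
                row[f"gnt_prob_{target}"] = prob
                row[f"gnt_class_{target}"] = trends.classify_attainment(prob)
            rows.append(row)
    pd.DataFrame(rows).to_csv(ws / "trends.csv", index=False)
    return ["trends.csv"]


def _stage_validate(config: PipelineConfig, ws: Path) -> list[str]:
    scenario = scenario_from_netcdf(ws / "scenario.nc")
    clusters = pd.read_csv(ws / "clusters.csv")
    inputs = _load_model_inputs(ws, scenario)
    vc = config.validation
    seed = _stage_seed(config, "validate")

    points = pd.DataFrame(
        {
            "lon": clusters["lon"],
            "lat": clusters["lat"],
            "size": clusters["weight"] * clusters["N"],
        }
    )
    partition = validation.bitree_partition(points, vc.target_size, vc.min_size)
    folds = validation.assign_folds(partition, vc.k_folds, seed)

    row, col = scenario.grid.cell_index(clusters["lon"], clusters["lat"])
    year = clusters["year"].to_numpy(int)
    # score on unit-year aggregates at each admin level
    unit_maps = {
        0: scenario.country_map[row, col] * 10000 + year,
        1: scenario.admin1_map[row, col] * 10000 + year,
        2: scenario.admin2_map[row, col] * 10000 + year,
    }
    N = clusters["N"].to_numpy(float)
    metrics_rows = []
    for variant in vc.variants:
        mc = config.model.model_config_obj(
            variant=variant, n_draws=vc.n_draws, n_hyper_draws=vc.n_hyper_draws
        )
        stacker_obs_all = inputs.stackers[1].obs

        def fit_predict(train, test, fold, mc=mc):
            fit = fit_stage(
                train, inputs, 1, mc, seed=seed + fold,
                stacker_obs=stacker_obs_all[train.index.to_numpy()],
            )
            return fit.predict_points(
                inputs, test["lon"], test["lat"], test["year"],
                stacker_obs=stacker_obs_all[test.index.to_numpy()],
                include_nugget=True,
                rng=np.random.default_rng(seed + 1000 + fold),
            )

        oos = validation.cross_validate(fit_predict, clusters, folds)
        full_fit = fit_stage(
            clusters, inputs, 1, mc, seed=seed, stacker_obs=stacker_obs_all
        )
        ins = full_fit.predict_points(
            inputs, clusters["lon"], clusters["lat"], clusters["year"],
            stacker_obs=stacker_obs_all, include_nugget=True,
            rng=np.random.default_rng(seed + 2000),
        )
        rng = np.random.default_rng(seed + 3000)
        for label, pred in (("out_of_sample", oos), ("in_sample", ins)):
            sampled = rng.binomial(
                N.astype(int)[None, :], np.clip(pred, 0, 1)
            ) / N[None, :]
            for level, labels in unit_maps.items():
                m = validation.validation_metrics(clusters, pred, labels, sampled)
                metrics_rows.append({"variant": variant, "sample": label,
                                     "level": level, **m})
    pd.DataFrame(metrics_rows).to_csv(ws / "cv_metrics.csv", index=False)
    return ["cv_metrics.csv"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "stack": _stage_stack,
    "fit": _stage_fit,
    "postest": _stage_postest,
    "rake": _stage_rake,
    "project": _stage_project,
    "validate": _stage_validate,
}


def run_stage(stage: str, config: PipelineConfig, workspace: str | Path,
              force: bool = False) -> Path:
    """Run one pipeline stage in the workspace; no-op when up to date."""
    if stage not in _STAGE_FNS:
        raise PipelineError(f"unknown stage '{stage}'; one of {STAGES}")
    ws = Path(workspace)
    ws.mkdir(parents=True, exist_ok=True)
    input_hashes = _check_prereqs(ws, stage)
    if not force and _stage_is_current(ws, stage, config, input_hashes):
        logger.info("stage '%s' is up to date; skipping", stage)
        return ws
    logger.info("running stage '%s'", stage)
    outputs = _STAGE_FNS[stage](config, ws)
    _write_stage_manifest(ws, stage, config, input_hashes, outputs)
    return ws


def run_all(config: PipelineConfig, workspace: str | Path,
            force: bool = False) -> Path:
    for stage in STAGES:
        run_stage(stage, config, workspace, force=force)
    return Path(workspace)
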