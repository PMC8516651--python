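"""Synthetic study scenario with known ground truth.

Emulates the inputs of a multi-country anemia-severity mapping study:
gridded covariates, population, elevation, a nested admin-0/1/2 hierarchy,
cluster survey microdata with woman-level hemoglobin, polygon-referenced
areal observations, and a national calibration series.  The generating
process is exactly the structure the geostatistical model assumes — logit
prevalence = intercept + covariate effects + Matérn⊗AR1 field + country
effect, with a continuation-ratio severity decomposition and a
per-cluster-stage nugget — so recovery and calibration tests against the
stored truth are well-specified.

Hemoglobin microdata are built for round-trip testability: a severity
category is drawn from the truth surfaces, an adjusted hemoglobin value is
drawn uniformly within that category's WHO band, and the configured
elevation/smoking decrements are then *added* to produce the raw value, so
re-running the adjustment + thresholding pipeline recovers the generating
category exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grids import GridSpec
from .hemoglobin import AdjustmentTables, SeverityThresholds
from .kronecker import GPHyperparameters, SpaceTimeCovariance

__all__ = [
    "TruthScenario",
    "simulate_space_time_field",
    "build_default_scenario",
    "simulate_cluster_microdata",
    "simulate_areal_observations",
    "generate_national_series",
    "make_admin_polygons",
]

STAGES = ("anemic", "mild_given_anemic", "severe_given_modsev")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclasses.dataclass
class TruthScenario:
    """Everything the pipeline consumes plus the generating truth.

    ``stage_truths`` holds three probability surfaces of shape
    (n_years, n_rows, n_cols): overall anemia, mild conditional on anemic,
    and severe conditional on moderate-or-severe.  ``marginal_truth(cat)``
    derives the marginal severity surfaces from them.
    """

    grid: GridSpec
    beta0: tuple[float, float, float]
    covariate_effects: dict[str, float]
    gp_params: GPHyperparameters
    country_effects: np.ndarray
    stage_truths: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray]
    population: np.ndarray
    elevation: np.ndarray
    country_map: np.ndarray
    admin1_map: np.ndarray
    admin2_map: np.ndarray
    barren_mask: np.ndarray
    seed: int
    adjustment_tables: AdjustmentTables = dataclasses.field(
        default_factory=AdjustmentTables
    )
    thresholds: SeverityThresholds = dataclasses.field(
        default_factory=SeverityThresholds
    )

    def __post_init__(self) -> None:
        for name, surf in self.stage_truths.items():
            if surf.shape != (self.grid.n_years, self.grid.n_rows, self.grid.n_cols):
                raise ValueError(f"stage surface {name} has wrong shape")
            if np.any((surf < 0) | (surf > 1)):
                raise ValueError(f"stage surface {name} outside [0, 1]")
        if np.any(self.population < 0):
            raise ValueError("population must be non-negative")

    @property
    def n_countries(self) -> int:
        return int(self.country_map.max()) + 1

    def marginal_truth(self, category: str) -> np.ndarray:
        """Marginal prevalence surface for overall/mild/moderate/severe."""
        p = self.stage_truths["anemic"]
        pm = self.stage_truths["mild_given_anemic"]
        ps = self.stage_truths["severe_given_modsev"]
        if category == "overall":
            return p
        if category == "mild":
            return p * pm
        if category == "severe":
            return p * (1 - pm) * ps
        if category == "moderate":
            return p * (1 - pm) * (1 - ps)
        raise KeyError(category)

    def category_probabilities(self, year_idx, row, col) -> np.ndarray:
        """(n, 4) probabilities of (non, mild, moderate, severe) at cells."""
        p = self.stage_truths["anemic"][year_idx, row, col]
        pm = self.stage_truths["mild_given_anemic"][year_idx, row, col]
        ps = self.stage_truths["severe_given_modsev"][year_idx, row, col]
        mild = p * pm
        severe = p * (1 - pm) * ps
        moderate = p - mild - severe
        return np.stack([1 - p, mild, moderate, severe], axis=-1)


def simulate_space_time_field(
    grid: GridSpec, params: GPHyperparameters, seed, size: int = 1
) -> np.ndarray:
    """Zero-mean ω²·Matérn(ν=2, κ) ⊗ AR1(ρ) field over cells × years.

    Returns shape (n_years, n_rows, n_cols), or with a leading replicate
    axis when ``size > 1``.  A zero-variance limit (ω² ≤ 1e-12) returns an
    exactly-zero field.
    """
    if params.omega2 <= 1e-12:
        out = np.zeros((size, grid.n_years, grid.n_rows, grid.n_cols))
        return out[0] if size == 1 else out
    lon, lat = grid.cell_centers()
    cells = np.column_stack([lon.ravel(), lat.ravel()])
    cov = SpaceTimeCovariance(
        cells, grid.n_years, params.omega2, params.delta, params.rho, params.nu
    )
    rng = np.random.default_rng(seed)
    draws = cov.sample(rng, size=size)  # (size, n_cells * n_years), space-major
    out = (
        draws.reshape(size, grid.n_cells, grid.n_years)
        .transpose(0, 2, 1)
        .reshape(size, grid.n_years, grid.n_rows, grid.n_cols)
    )
    return out[0] if size == 1 else out


def _admin_maps(grid: GridSpec, n_countries: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested admin rasters: countries as column bands, each split 2x2."""
    col_band = np.minimum(
        (np.arange(grid.n_cols) * n_countries) // grid.n_cols, n_countries - 1
    )
    country = np.broadcast_to(col_band, (grid.n_rows, grid.n_cols)).copy()
    south = (np.arange(grid.n_rows) < grid.n_rows // 2).astype(int)
    admin1 = country * 2 + np.broadcast_to(south[:, None], country.shape)
    # split each admin1 east/west at the middle of its country band
    admin2 = np.zeros_like(admin1)
    for c in range(n_countries):
        cols = np.nonzero(col_band == c)[0]
        east = np.isin(np.arange(grid.n_cols), cols[len(cols) // 2 :]).astype(int)
        in_c = country == c
        admin2[in_c] = (admin1 * 2 + east[None, :])[in_c]
    return country, admin1, admin2


def make_admin_polygons(grid: GridSpec, admin_map: np.ndarray) -> dict[int, object]:
    """Rectangular shapely polygons for each unit of an admin raster."""
    from shapely.geometry import box

    half = grid.cell_size / 2
    polys = {}
    for uid in np.unique(admin_map):
        rows, cols = np.nonzero(admin_map == uid)
        polys[int(uid)] = box(
            grid.lons[cols.min()] - half,
            grid.lats[rows.min()] - half,
            grid.lons[cols.max()] + half,
            grid.lats[rows.max()] + half,
        )
    return polys


def build_default_scenario(
    seed: int = 0,
    n_rows: int = 20,
    n_cols: int = 20,
    cell_size: float = 0.5,
    origin_lon: float = 30.0,
    origin_lat: float = -10.0,
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017, 2018),
    n_countries: int = 3,
    beta0: tuple[float, float, float] = (-0.5, 0.2, -1.6),
    covariate_effects: dict[str, float] | None = None,
    gp_params: GPHyperparameters | None = None,
) -> TruthScenario:
    """Default toy scenario: 20 x 20 grid, 6 years, 3 countries, 2 covariates.

    Sized so a full pipeline run (simulation through validation) completes in
    minutes on one CPU while keeping every structural feature of the model:
    a smooth spatial field with visible temporal persistence (ρ = 0.8, range
    δ = 4° on a 10° domain, ω² = 0.3), modest country effects, and severity
    stages with their own weaker fields.
    """
    grid = GridSpec(origin_lon, origin_lat, cell_size, n_rows, n_cols, years)
    rng = np.random.default_rng(seed)
    effects = covariate_effects if covariate_effects is not None else {
        "cov0": 0.6, "cov1": -0.4,
    }
    params = gp_params or GPHyperparameters(
        omega2=0.3, delta=4.0, rho=0.8, gamma2_country=0.09, sigma2_nugget=0.05
    )

    lon, lat = grid.cell_centers()
    lon_u = (lon - lon.mean()) / (lon.max() - lon.min() + 1e-12)
    lat_u = (lat - lat.mean()) / (lat.max() - lat.min() + 1e-12)
    covariates: dict[str, np.ndarray] = {}
    if "cov0" in effects:
        covariates["cov0"] = 2.0 * lon_u + np.sin(3 * np.pi * lat_u)
    if "cov1" in effects:
        covariates["cov1"] = 2.0 - 8.0 * (lon_u**2 + lat_u**2)
        covariates["cov1"] -= covariates["cov1"].mean()
    for name in effects:
        if name not in covariates:  # extra covariates: smooth random fields
            base = rng.standard_normal((n_rows, n_cols))
            covariates[name] = _smooth(base, 3)

    country_map, admin1_map, admin2_map = _admin_maps(grid, n_countries)
    country_effects = rng.normal(0.0, np.sqrt(params.gamma2_country), n_countries)

    # population: smooth lognormal density with a sparse south-west corner;
    # mean ≈ 65 persons/km² at 0.5° cells, typical of rural LMIC settings
    pop = np.exp(1.0 + 0.8 * _smooth(rng.standard_normal((n_rows, n_cols)), 2))
    pop = 2.0e5 * pop / pop.mean()
    pop[-3:, :2] *= 1e-4  # near-empty cells, exercised by the mask
    barren = np.zeros((n_rows, n_cols), dtype=bool)
    barren[-2:, 2:4] = True

    elevation = np.clip(
        3000.0 * (lon - lon.min()) / (lon.max() - lon.min())
        + 150.0 * _smooth(rng.standard_normal((n_rows, n_cols)), 2),
        0.0,
        None,
    )

    # stage-specific latent fields; conditional stages get weaker fields
    field_seeds = np.random.SeedSequence(seed).spawn(3)
    cov_term = sum(effects[k] * covariates[k] for k in effects)
    stage_truths = {}
    for s, name in enumerate(STAGES):
        p = params if s == 0 else dataclasses.replace(
            params, omega2=params.omega2 / 2
        )
        field = simulate_space_time_field(grid, p, field_seeds[s])
        lin = beta0[s] + field
        if s == 0:
            lin = lin + cov_term[None, :, :] + country_effects[country_map][None, :, :]
        elif s == 1:
            lin = lin + 0.5 * cov_term[None, :, :]
        stage_truths[name] = _sigmoid(lin)

    return TruthScenario(
        grid=grid,
        beta0=tuple(beta0),
        covariate_effects=dict(effects),
        gp_params=params,
        country_effects=country_effects,
        stage_truths=stage_truths,
        covariates=covariates,
        population=pop,
        elevation=elevation,
        country_map=country_map,
        admin1_map=admin1_map,
        admin2_map=admin2_map,
        barren_mask=barren,
        seed=int(seed),
    )


def _smooth(arr: np.ndarray, passes: int) -> np.ndarray:
    """Cheap box smoothing used to make plausible-looking rasters."""
    from scipy.ndimage import uniform_filter

    out = arr.astype(float)
    for _ in range(passes):
        out = uniform_filter(out, size=5, mode="nearest")
    out = out - out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


# band used to draw hemoglobin for non-anemic women: [overall cutoff, +4)
_NON_ANEMIC_SPAN = 4.0


def _hb_band(category: np.ndarray, pregnant: np.ndarray, thr: SeverityThresholds):
    cuts = thr.cuts(pregnant)
    severe_b, moderate_b, overall = cuts[:, 0], cuts[:, 1], cuts[:, 2]
    lo = np.select(
        [category == "severe", category == "moderate", category == "mild"],
        [4.0, severe_b, moderate_b],
        default=overall,
    )
    hi = np.select(
        [category == "severe", category == "moderate", category == "mild"],
        [severe_b, moderate_b, overall],
        default=overall + _NON_ANEMIC_SPAN,
    )
    return lo, hi


def simulate_cluster_microdata(
    scenario: TruthScenario,
    n_clusters: int = 150,
    mean_cluster_size: float = 35.0,
    seed: int = 0,
    pregnant_rate: float = 0.1,
    smoker_rate: float = 0.15,
) -> pd.DataFrame:
    """Woman-level records for population-weighted survey clusters.

    Cluster cells are drawn with probability proportional to population and
    each cluster observes one survey year.  Per cluster and stage an iid
    nugget N(0, σ²) perturbs the truth logit, matching the model's
    observation-level noise.  Raw hemoglobin is the in-band adjusted value
    plus the scenario's configured elevation/smoking decrements.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    grid = scenario.grid
    pop = scenario.population.ravel()
    if pop.sum() <= 0:
        raise ValueError("population raster is empty")
    rng = np.random.default_rng(seed)

    cells = rng.choice(grid.n_cells, size=n_clusters, p=pop / pop.sum())
    rows, cols = np.unravel_index(cells, (grid.n_rows, grid.n_cols))
    year_idx = rng.integers(0, grid.n_years, size=n_clusters)
    sizes = np.maximum(1, rng.poisson(mean_cluster_size, size=n_clusters))

    sigma = np.sqrt(scenario.gp_params.sigma2_nugget)
    stage_p = np.column_stack(
        [scenario.stage_truths[name][year_idx, rows, cols] for name in STAGES]
    )
    eps = np.isclose(stage_p, 0) | np.isclose(stage_p, 1)
    noisy = np.where(
        eps, stage_p, _sigmoid(_logit(np.clip(stage_p, 1e-12, 1 - 1e-12))
                               + rng.normal(0, sigma, stage_p.shape))
    )
    p_an, p_mild_g, p_sev_g = noisy.T
    mild = p_an * p_mild_g
    severe = p_an * (1 - p_mild_g) * p_sev_g
    moderate = p_an - mild - severe
    cat_probs = np.column_stack([1 - p_an, mild, moderate, severe])

    frames = []
    woman = 0
    for c in range(n_clusters):
        n = sizes[c]
        cats = np.array(["non_anemic", "mild", "moderate", "severe"], dtype=object)[
            rng.choice(4, size=n, p=np.clip(cat_probs[c], 0, None) / cat_probs[c].clip(0).sum())
        ]
        pregnant = rng.random(n) < pregnant_rate
        smoker = rng.random(n) < smoker_rate
        lo, hi = _hb_band(cats, pregnant, scenario.thresholds)
        adjusted = rng.uniform(lo, hi)
        elev = scenario.elevation[rows[c], cols[c]]
        raw = (
            adjusted
            + scenario.adjustment_tables.elevation_decrement(np.full(n, elev))
            + np.where(smoker, scenario.adjustment_tables.smoking_decrement, 0.0)
        )
        frames.append(
            pd.DataFrame(
                {
                    "woman_id": np.arange(woman, woman + n),
                    "cluster_id": f"cl{c:04d}",
                    "lon": grid.lons[cols[c]],
                    "lat": grid.lats[rows[c]],
                    "year": grid.years[year_idx[c]],
                    "age": rng.integers(15, 50, size=n),
                    "pregnant": pregnant,
                    "smoker": smoker,
                    "elevation": elev,
                    "raw_hb": raw,
                    "provenance": "raw",
                    "true_category": cats,
                }
            )
        )
        woman += n
    return pd.concat(frames, ignore_index=True)


def simulate_areal_observations(
    scenario: TruthScenario,
    polygons: dict[int, object] | None = None,
    n_polygons: int = 6,
    seed: int = 0,
    n_per_polygon: int = 1000,
) -> tuple[pd.DataFrame, dict[int, object]]:
    """Polygon-referenced multinomial severity counts.

    Counts are drawn from the population-weighted mean truth over each
    polygon; polygons default to a seeded sample of admin-2 rectangles.
    Polygons with zero population are skipped with a warning.
    """
    import logging

    from .hemoglobin import polygon_cells

    rng = np.random.default_rng(seed)
    grid = scenario.grid
    if polygons is None:
        admin2 = make_admin_polygons(grid, scenario.admin2_map)
        ids = rng.choice(sorted(admin2), size=min(n_polygons, len(admin2)), replace=False)
        polygons = {int(i): admin2[int(i)] for i in ids}

    records = []
    kept: dict[int, object] = {}
    for pid, poly in polygons.items():
        rows, cols = polygon_cells(poly, grid)
        pops = scenario.population[rows, cols]
        if len(rows) == 0 or pops.sum() <= 0:
            logging.getLogger(__name__).warning(
                "skipping polygon %s with zero population", pid
            )
            continue
        year_idx = int(rng.integers(0, grid.n_years))
        probs = scenario.category_probabilities(year_idx, rows, cols)
        mean_probs = np.average(probs, axis=0, weights=pops)
        counts = rng.multinomial(n_per_polygon, mean_probs / mean_probs.sum())
        records.append(
            {
                "polygon_id": int(pid),
                "year": grid.years[year_idx],
                "N": n_per_polygon,
                "anemic": int(counts[1:].sum()),
                "mild": int(counts[1]),
                "moderate": int(counts[2]),
                "severe": int(counts[3]),
            }
        )
        kept[int(pid)] = poly
    return pd.DataFrame(records), kept


def national_truth(scenario: TruthScenario) -> pd.DataFrame:
    """Population-weighted national overall-anemia truth per country-year."""
    grid = scenario.grid
    truth = scenario.stage_truths["anemic"]
    rows = []
    for c in range(scenario.n_countries):
        sel = scenario.country_map == c
        w = scenario.population[sel]
        for t, year in enumerate(grid.years):
            rows.append(
                {
                    "country": c,
                    "year": year,
                    "value": float(np.average(truth[t][sel], weights=w)),
                }
            )
    return pd.DataFrame(rows)


def generate_national_series(
    scenario: TruthScenario,
    bias_factor: float | dict[tuple[int, int], float] = 1.0,
    years: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """External calibration series = national truth × bias factor.

    By default covers every scenario year except the last, so the raking
    stage must extrapolate the final year.  With bias 1.0 the series equals
    the aggregated truth exactly (raking becomes an identity test).
    """
    truth = national_truth(scenario)
    if years is None:
        years = scenario.grid.years[:-1]
    truth = truth[truth["year"].isin(years)].reset_index(drop=True)

    def factor(row):
        if isinstance(bias_factor, dict):
            return bias_factor.get((row["country"], row["year"]), 1.0)
        return bias_factor

    f = truth.apply(factor, axis=1).astype(float)
    if (f <= 0).any():
        raise ValueError("bias_factor must be positive")
    truth["value"] = truth["value"] * f
    return truth
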