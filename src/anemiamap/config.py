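"""Pydantic-validated pipeline configuration.

The configuration is the single source of study conditions: scenario sizes
and truth parameters, adjustment tables, learner settings, model variant and
priors, post-estimation constants, raking, trend and validation settings.
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .aggregation import DisabilityWeights
from .gp import ModelConfig
from .hemoglobin import AdjustmentTables, PointsPerCellRule, SeverityThresholds
from .kronecker import GPHyperparameters

__all__ = ["PipelineConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Block):
    n_rows: int = 20
    n_cols: int = 20
    cell_size: float = 0.5
    origin_lon: float = 30.0
    origin_lat: float = -10.0
    years: list[int] = [2013, 2014, 2015, 2016, 2017, 2018]
    n_countries: int = 3
    beta0: list[float] = [-0.5, 0.2, -1.6]
    covariate_effects: dict[str, float] = {"cov0": 0.6, "cov1": -0.4}
    omega2: float = 0.3
    delta: float = 4.0
    rho: float = 0.8
    gamma2_country: float = 0.09
    sigma2_nugget: float = 0.05
    n_clusters: int = 150
    mean_cluster_size: float = 35.0
    n_polygons: int = 4
    areal_n: int = 1000
    national_bias: float = 1.15
    pregnant_rate: float = 0.1
    smoker_rate: float = 0.15

    def gp_params(self) -> GPHyperparameters:
        return GPHyperparameters(
            omega2=self.omega2,
            delta=self.delta,
            rho=self.rho,
            gamma2_country=self.gamma2_country,
            sigma2_nugget=self.sigma2_nugget,
        )


class AdjustmentConfig(_Block):
    elevation_bins: list[list[float]] | None = None
    smoking_decrement: float = 0.3
    thresholds_non_pregnant: list[float] = [8.0, 11.0, 12.0]
    thresholds_pregnant: list[float] = [7.0, 10.0, 11.0]

    def tables(self) -> AdjustmentTables:
        if self.elevation_bins is None:
            return AdjustmentTables(smoking_decrement=self.smoking_decrement)
        return AdjustmentTables(
            elevation_bins=tuple(tuple(b) for b in self.elevation_bins),
            smoking_decrement=self.smoking_decrement,
        )

    def thresholds(self) -> SeverityThresholds:
        return SeverityThresholds(
            non_pregnant=tuple(self.thresholds_non_pregnant),
            pregnant=tuple(self.thresholds_pregnant),
        )


class PreprocessConfig(_Block):
    cells_per_point: int = 10
    min_points: int = 1
    max_points: int = 100

    def rule(self) -> PointsPerCellRule:
        return PointsPerCellRule(self.cells_per_point, self.min_points, self.max_points)


class StackerConfig(_Block):
    cv_folds: int = 5
    gam_knots: int = 5
    gam_alpha: float = 1.0
    brt_trees: int = 150
    brt_depth: int = 2
    brt_learning_rate: float = 0.1
    brt_subsample: float = 0.9
    lasso_alpha: float = 1e-3

    def learner_config(self) -> dict:
        return self.model_dump(exclude={"cv_folds"})


class ModelBlock(_Block):
    variant: str = "stack_gp"
    knot_spacing_cells: int = 3
    n_draws: int = 1000
    n_hyper_draws: int = 25
    fixed_effect_prior_sd: float = 5.0
    priors: dict[str, list[float]] | None = None

    @field_validator("variant")
    @classmethod
    def _check_variant(cls, v):
        if v not in ("raw", "raw_gp", "stack", "stack_gp"):
            raise ValueError(f"unknown model variant {v!r}")
        return v

    def model_config_obj(self, **overrides) -> ModelConfig:
        kwargs = dict(
            variant=self.variant,
            knot_spacing_cells=self.knot_spacing_cells,
            n_draws=self.n_draws,
            n_hyper_draws=self.n_hyper_draws,
            fixed_effect_prior_sd=self.fixed_effect_prior_sd,
            priors={k: tuple(v) for k, v in self.priors.items()} if self.priors else None,
        )
        kwargs.update(overrides)
        return ModelConfig(**kwargs)


class PostestConfig(_Block):
    mask_threshold_per_km2: float = 10.0
    wra_fraction: float = 0.25
    dw_mild: float = 0.004
    dw_moderate: float = 0.052
    dw_severe: float = 0.149

    def disability_weights(self) -> DisabilityWeights:
        return DisabilityWeights(self.dw_mild, self.dw_moderate, self.dw_severe)


class RakingConfig(_Block):
    enabled: bool = True


class TrendsConfig(_Block):
    aroc_gamma: float = 1.0
    origin_year: int = 2000
    baseline_year: int = 2012
    target_years: list[int] = [2025, 2030]
    use_printed_formula: bool = False


class ValidationConfig(_Block):
    k_folds: int = 5
    target_size: float = 2000.0
    min_size: float = 500.0
    variants: list[str] = ["raw", "raw_gp", "stack", "stack_gp"]
    n_draws: int = 200
    n_hyper_draws: int = 10


class PipelineConfig(_Block):
    seed: int = 0
    scenario: ScenarioConfig = ScenarioConfig()
    adjustment: AdjustmentConfig = AdjustmentConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    stacker: StackerConfig = StackerConfig()
    model: ModelBlock = ModelBlock()
    postest: PostestConfig = PostestConfig()
    raking: RakingConfig = RakingConfig()
    trends: TrendsConfig = TrendsConfig()
    validation: ValidationConfig = ValidationConfig()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load YAML config (defaults if None); keyword blocks override."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return PipelineConfig(**data)
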