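import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from anemiamap.config import load_config
from anemiamap.hemoglobin import collapse_to_clusters
from anemiamap.pipeline import run_all
from anemiamap.synthetic import build_default_scenario, simulate_cluster_microdata

logging.getLogger("anemiamap").setLevel(logging.ERROR)

# Reduced problem sizes keep the full suite to desk scale: a 12x12 grid over
# four years for pipeline smoke/determinism runs, and modest draw counts
# wherever the check is about structure rather than Monte-Carlo precision.
SMALL_OVERRIDES = dict(
    seed=11,
    scenario={
        "n_rows": 12,
        "n_cols": 12,
        "years": [2015, 2016, 2017, 2018],
        "n_clusters": 80,
        "mean_cluster_size": 30.0,
        "n_polygons": 2,
        "national_bias": 0.9,
    },
    model={"n_draws": 100, "n_hyper_draws": 5},
    validation={
        "n_draws": 80,
        "n_hyper_draws": 4,
        "target_size": 800.0,
        "min_size": 200.0,
        "variants": ["stack", "stack_gp"],
    },
)

# The default study scenario (20x20 grid, 6 years, 3 countries) with draw
# counts sized for interval estimation rather than dense mapping.
DEFAULT_OVERRIDES = dict(
    seed=7,
    model={"n_draws": 250, "n_hyper_draws": 10},
    validation={"n_draws": 150, "n_hyper_draws": 5},
)


@pytest.fixture(scope="session")
def small_config():
    return load_config(None, **SMALL_OVERRIDES)


@pytest.fixture(scope="session")
def small_ws(small_config, tmp_path_factory):
    """One full pipeline run on the reduced scenario, shared across tests."""
    ws = tmp_path_factory.mktemp("small_ws")
    run_all(small_config, ws)
    return ws


@pytest.fixture(scope="session")
def default_config():
    return load_config(None, **DEFAULT_OVERRIDES)


@pytest.fixture(scope="session")
def default_ws(default_config, tmp_path_factory):
    """Default-scenario pipeline run (through projection), shared."""
    from anemiamap.pipeline import STAGES, run_stage

    ws = tmp_path_factory.mktemp("default_ws")
    for stage in STAGES:
        if stage == "validate":
            continue
        run_stage(stage, default_config, ws)
    return ws


@pytest.fixture(scope="session")
def scenario():
    """Default truth scenario used by generator-level tests."""
    return build_default_scenario(seed=5)


@pytest.fixture(scope="session")
def microdata(scenario):
    return simulate_cluster_microdata(
        scenario, n_clusters=60, mean_cluster_size=25, seed=6
    )


@pytest.fixture(scope="session")
def clusters(scenario, microdata):
    return collapse_to_clusters(
        microdata, scenario.adjustment_tables, scenario.thresholds
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
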