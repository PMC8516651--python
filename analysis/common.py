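"""Shared setup for the numbered analysis drivers.

All drivers operate on one workspace under ``scratch/`` (heavy artifacts:
NetCDF draws, rasters) and publish summary tables to ``results/``.  The
configuration below defines the study conditions: the default 20x20-cell,
six-year, three-country scenario, with 250 posterior draws for mapping and
150 for cross-validation.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

from anemiamap.config import load_config

ROOT = Path(__file__).resolve().parent.parent
WORKSPACE = ROOT / "scratch" / "workspace"
RESULTS = ROOT / "results"

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def study_config(seed: int = 7):
    return load_config(
        None,
        seed=seed,
        model={"n_draws": 250, "n_hyper_draws": 10},
        validation={"n_draws": 150, "n_hyper_draws": 5},
    )


def publish(*names: str) -> None:
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        shutil.copy(WORKSPACE / name, RESULTS / name)
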