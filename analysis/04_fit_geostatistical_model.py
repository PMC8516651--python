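"""Fit the continuation-ratio space-time GP model and draw surfaces.

Three independent binomial logit stages (anemic; mild | anemic; severe |
moderate-or-severe), each with constrained stacker weights, country
intercepts, a nugget, and a Matérn⊗AR1 Gaussian process on a knot lattice.
Posterior draws are composed into marginal severity surfaces.
"""

from common import WORKSPACE, publish, study_config

import numpy as np
import pandas as pd
import xarray as xr

from anemiamap.pipeline import run_stage, scenario_from_netcdf

if __name__ == "__main__":
    config = study_config()
    run_stage("fit", config, WORKSPACE)
    print(pd.read_csv(WORKSPACE / "hyperparams.csv").round(3).to_string(index=False))
    print(pd.read_csv(WORKSPACE / "stacker_weights.csv").round(3).to_string(index=False))
    ds = xr.open_dataset(WORKSPACE / "draws.nc", engine="scipy").load()
    ds.close()
    scenario = scenario_from_netcdf(WORKSPACE / "scenario.nc")
    est = ds["overall"].mean("draw").values
    truth = scenario.stage_truths["anemic"]
    print("correlation of posterior-mean overall anemia with truth: "
          f"{np.corrcoef(est.ravel(), truth.ravel())[0, 1]:.3f}")
    publish("hyperparams.csv", "stacker_weights.csv")
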