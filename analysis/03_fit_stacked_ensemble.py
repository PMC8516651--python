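"""Fit the three child learners per continuation-ratio stage.

Produces strictly out-of-sample logit-scale predictions at the observations
(cluster-stratified five-fold) and grid predictions from all-data refits;
these enter the geostatistical model as constrained covariates.
"""

from common import WORKSPACE, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("stack", config, WORKSPACE)
    obs = pd.read_csv(WORKSPACE / "stacker_obs.csv")
    print("stacker prediction spread (logit sd) per stage-1 learner:")
    print(obs[[c for c in obs.columns if c.startswith("s1_")]].std().round(3))
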