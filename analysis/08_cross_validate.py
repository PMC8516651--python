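"""Spatially stratified five-fold cross-validation of the model variants.

Bi-tree folds (weighted-median splits, minimum leaf sample 500) hold out
whole spatial blocks; each covariate/GP variant is refit per fold and scored
on admin-aggregated held-out observations (ME, RMSE, CoV, 95% coverage,
correlation).
"""

from common import WORKSPACE, publish, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("validate", config, WORKSPACE)
    cv = pd.read_csv(WORKSPACE / "cv_metrics.csv")
    oos = cv[cv["sample"] == "out_of_sample"]
    print("out-of-sample metrics by variant and admin level:")
    print(oos.pivot_table(index="variant", columns="level",
                          values=["rmse", "coverage", "correlation"]).round(3))
    publish("cv_metrics.csv")
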