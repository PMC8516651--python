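"""Simulate the synthetic study scenario.

Generates the full input set a mapping study consumes — covariate, population
and elevation rasters, a nested admin hierarchy, cluster survey microdata
with woman-level hemoglobin, polygon-referenced areal counts, and a biased
national calibration series — with the ground truth stored alongside.
"""

from common import WORKSPACE, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("simulate", config, WORKSPACE)
    micro = pd.read_csv(WORKSPACE / "microdata.csv")
    print(f"simulated {len(micro)} women in {micro['cluster_id'].nunique()} "
          f"clusters across {micro['year'].nunique()} survey years")
    print("severity mix:",
          micro["true_category"].value_counts(normalize=True).round(3).to_dict())
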