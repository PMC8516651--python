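"""Hemoglobin adjustment, WHO thresholding, and cluster collapse.

Turns woman-level records into stage-specific binomial cluster observations
and resamples the polygon-referenced records to population-weighted
pseudo-points whose weights sum to one.
"""

from common import WORKSPACE, publish, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("preprocess", config, WORKSPACE)
    clusters = pd.read_csv(WORKSPACE / "clusters.csv")
    direct = (clusters["weight"] == 1).sum()
    print(f"{len(clusters)} cluster observations "
          f"({direct} directly geolocated, {len(clusters) - direct} resampled "
          f"pseudo-points); total effective sample "
          f"{(clusters['weight'] * clusters['N']).sum():.0f} women")
    publish("clusters.csv")
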