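"""Masked population-weighted aggregation of the unraked surfaces."""

from common import WORKSPACE, publish, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("postest", config, WORKSPACE)
    prev = pd.read_csv(WORKSPACE / "admin_prevalence_unraked.csv")
    nat = prev.query("level == 0 and indicator == 'overall'")
    last = nat[nat["year"] == nat["year"].max()]
    print("unraked national overall anemia prevalence, final year:")
    print(last[["unit", "mean", "lower", "upper"]].round(3).to_string(index=False))
    publish("admin_prevalence_unraked.csv")
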