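"""Weighted AROCs, logit-space projections, and GNT attainment.

Draw-level annualized rates of change (recent years up-weighted, γ = 1) are
applied in logit space to the final estimation year, and the probability of
halving anemia prevalence relative to the baseline year is the fraction of
paired posterior draws meeting the reduced baseline.
"""

from common import WORKSPACE, publish, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("project", config, WORKSPACE)
    tr = pd.read_csv(WORKSPACE / "trends.csv")
    nat = tr[tr["level"] == 0]
    print("national trend summary:")
    cols = ["unit", "aroc_mean", "proj_2025_mean", "gnt_prob_2025",
            "proj_2030_mean", "gnt_prob_2030"]
    print(nat[cols].round(3).to_string(index=False))
    a2 = tr[tr["level"] == 2]
    on_track = (a2["gnt_prob_2030"] > 0.5).mean()
    print(f"\n{on_track:.0%} of admin-2 units have >50% probability of "
          "halving anemia by 2030")
    publish("trends.csv")
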