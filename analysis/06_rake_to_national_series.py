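"""Rake draws to the national calibration series; counts, YLDs, classes.

Per-draw raking factors (external / modelled national aggregate) are
linearly interpolated across years, carried into the unobserved final year,
and multiplied into the severity surfaces.  Affected counts, YLDs,
public-health-problem classes and subnational inequality are computed from
the raked draws.
"""

from common import WORKSPACE, publish, study_config

import pandas as pd

from anemiamap.pipeline import run_stage

if __name__ == "__main__":
    config = study_config()
    run_stage("rake", config, WORKSPACE)
    counts = pd.read_csv(WORKSPACE / "admin_counts.csv")
    nat = counts.query("level == 0 and indicator == 'overall'")
    last = nat[nat["year"] == nat["year"].max()]
    print("anemic WRA (raked), final year, per country:")
    print(last[["unit", "mean", "lower", "upper"]].round(0).to_string(index=False))
    print("\nsubnational inequality (admin-2, final year):")
    print(pd.read_csv(WORKSPACE / "inequality.csv").round(3).to_string(index=False))
    publish("raking_table.csv", "admin_prevalence.csv", "admin_counts.csv",
            "admin_ylds.csv", "public_health_class.csv", "inequality.csv")
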