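"""Fit the exposure x outcome x model-tier mortality grid.

Runs the three exposures (unprocessed red, processed, combined) against
all-cause and CVD mortality under the three covariate tiers, with five
chained-equation imputations Rubin-pooled per cell, quartile hazard ratios,
quartile-median trend tests, and uncalibrated plus regression-calibrated
90th-vs-0 contrasts (BCa interval at B=200 for the combined/all-cause/
model-3 cell, the headline estimate).

Writes results/models/{report.json, table_grid.csv}.
"""

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from dietcal.pipeline import AnalysisSpec, run_full_analysis

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "models"

if __name__ == "__main__":
    cohort = pd.read_csv(ROOT / "results" / "sim" / "cohort.csv")
    substudy = pd.read_csv(ROOT / "results" / "sim" / "substudy.csv")
    # m=3 imputations and B=200 bootstrap rounds keep this demonstration
    # run to a few minutes; the library defaults are m=5 / B=4000
    spec = AnalysisSpec(
        outcomes=["all_cause", "cvd"],
        m=3,
        B=200,
        seed=20260929,
    )
    t0 = time.time()
    report = run_full_analysis(cohort, substudy, spec)
    print(f"grid of {len(report['grid'])} cells in {time.time() - t0:.0f}s")

    rows = []
    for key, cell in report["grid"].items():
        exposure, outcome, tier = key.split("|")
        if "error" in cell:
            print(f"  {key}: FAILED ({cell['error']})")
            continue
        unc, cal = cell["uncalibrated_90th_vs_0"], cell["calibrated_90th_vs_0"]
        rows.append(
            {
                "exposure": exposure, "outcome": outcome, "model": tier,
                "n_events": cell["n_events"],
                "q4_hr": cell["quartile_hr"]["q4"]["hr"],
                "trend_p": cell["trend_p"],
                "hr_90_vs_0": unc["hr"], "hr_lo": unc["ci_low"], "hr_hi": unc["ci_high"],
                "cal_hr_90_vs_0": cal["hr"], "cal_lo": cal["ci_low"], "cal_hi": cal["ci_high"],
            }
        )
    table = pd.DataFrame(rows)
    print(table.round(3).to_string(index=False))
    amplified = (table["cal_hr_90_vs_0"] > table["hr_90_vs_0"]).mean()
    print(f"\ncalibrated HR exceeds uncalibrated in {100 * amplified:.0f}% of cells "
          "(classical-error attenuation corrected)")

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    table.to_csv(OUT / "table_grid.csv", index=False)
    print(f"wrote {OUT}")
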