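"""Week-based dosing/dialysis scenario grid with bioequivalence statistics.

Simulates virtual Fabry cohorts to steady state under each candidate regimen
(82/123 mg QW or QOW with twice- or thrice-weekly dialysis) and compares
exposure against the reference: normal renal function on 123 mg every other
day.  A regimen is attractive when Cavg is bioequivalent (GMR 90% CI within
0.80-1.25), Cmax stays adequate, and the trough falls below the assay LLOQ so
the chaperone can wash out between doses.

Run with a small cohort here for speed; the acceptance script runs n = 100.
"""

import pandas as pd

from dialypk import RunConfig, run_scenario_table

pd.set_option("display.width", 200)

table = run_scenario_table(RunConfig(n_subjects=25, seed=2024))
cols = ["scenario", "dialysis", "regimen", "gmr_cavg", "be_cavg",
        "gmr_cmax", "be_cmax", "pct_cmax_above", "pct_ctrough_blq"]
print(table[cols].round(3).to_string(index=False))
# gmr_* ~ 1 and be_* True mean the ESRD regimen reproduces the reference
# exposure; pct_cmax_above is the share of subjects peaking above 10 uM
# (1631.7 ng/mL) and pct_ctrough_blq the share washing out below 5.88 ng/mL.
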