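#!/usr/bin/env python
"""Score every plan with the nine-metric PQM table and summarise totals.

Regenerates the deterministic cohort, applies the shipped scoring windows
(PTV D2/HI/CI, bladder D15/D50, femoral-head D25/D40 left and right, each
worth 0-10 points) and prints the per-strategy total (0-90) as
mean +- standard deviation.

Writes results/pqm.csv and results/pqm_summary.csv.
"""

from pathlib import Path

from planqa import run_cohort_analysis

results = run_cohort_analysis(n_patients=20, master_seed=1, evaluate_goal_sets=False)
pqm = results["pqm"]
Path("results").mkdir(exist_ok=True)
pqm.to_csv("results/pqm.csv", index=False)

summary = pqm.groupby("strategy")["total"].agg(["mean", "std", "min", "max"]).round(2)
summary.to_csv("results/pqm_summary.csv")
print("total PQM score (0-90) per strategy:")
print(summary.to_string())

score_cols = [c for c in pqm.columns if c.startswith("score_")]
print("\nper-metric mean scores:")
print(pqm.groupby("strategy")[score_cols].mean().round(2).to_string())
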