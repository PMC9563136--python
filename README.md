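# planqa

Plan-quality evaluation and robustness analysis for automatic radiotherapy
planning, exercised end to end on synthetic pelvis phantoms.

## The problem

Automatic planning for rectal-cancer VMAT comes in two flavours.
*Script-based* planning turns a fixed set of clinical goals into optimization
objectives; it is stable but blind to patient anatomy, so a single goal
template is too loose for some patients and infeasible for others (for
example when the bladder overlaps the target).  *Hybrid* planning first
predicts an achievable dose distribution for the patient, replaces each
organ-at-risk (OAR) goal with the corresponding index of the prediction, and
only then runs script-based optimization — a personalised goal template.

This package implements the evaluation side of that comparison for cohorts
of plans: dose-volume histogram (DVH) indices, conformity and homogeneity
indices, a nine-metric plan-quality score, the prediction-driven goal-update
workflow, and the paired statistical protocol — plus a synthetic cohort
generator so the whole pipeline runs without any patient data.

## The quantities

For a structure with voxel doses sorted descending,

- **Dx** — minimum dose to the hottest x% of the structure:
  `Dx = s[k-1]`, `k = ceil(x/100 · N)` (full-voxel convention);
- **Vx** — percent of the structure receiving at least a threshold dose
  (inclusive);
- **CI** (conformity, Paddick form) —
  `CI = (TV_RI/TV) · (TV_RI/V_RI)`, with the reference isodose at 95% of
  the prescription and V_RI counted inside the body; 1 is perfect
  conformity;
- **HI** (homogeneity) — `HI = (D2 − D98)/D_prescription`; 0 is perfectly
  uniform;
- **PQM** — each of nine metrics (PTV D2, HI, CI; bladder D15, D50;
  femoral-head D25, D40 on both sides) is scored piecewise-linearly over a
  value window onto 0–10 points; the plan total is their sum, 0–90.

Plans carry a 5000 cGy / 25-fraction prescription with D95 coverage.  Goal
templates come in three levels (easy / moderate / hard) that share the
prescription but tighten the PTV max-dose and the bladder and femoral-head
mean-dose limits.

## Worked example

```python
from planqa import (generate_phantom, predict_dose, preset_goals,
                    update_goals, STRATEGY_PRESETS)

patient = generate_phantom(seed=5)                      # 80^3 pelvis, 2.5 mm voxels
predicted = predict_dose(patient, STRATEGY_PRESETS["hybrid_moderate"])
goals = preset_goals("hard")                            # bladder mean < 2000 cGy, ...
personal = update_goals(goals, predicted, patient)
for before, after in zip(goals.goals, personal.goals):
    print(f"{before.structure:13s} {before.kind:17s} "
          f"{before.limit:7.1f} -> {after.limit:7.1f} cGy")
```

prints

```
PTV           prescription_D95   5000.0 ->  5000.0 cGy
PTV           max_dose           5100.0 ->  5100.0 cGy
bladder       mean_dose          2000.0 ->  2684.4 cGy
femur_head_L  mean_dose           900.0 ->  1539.5 cGy
femur_head_R  mean_dose           900.0 ->  1539.5 cGy
```

Target goals are untouched; the hard OAR limits, infeasible for this
anatomy, are *loosened* to what the prediction says is achievable — the
personalisation can relax as well as tighten.

The numbered drivers under `analysis/` run the full cohort study
(20 patients × 7 strategies, deterministic from a master seed):

1. `01_simulate_cohort.py` — phantoms + dose simulation, D95 calibration check;
2. `02_evaluate_plans.py` — metric panel and clinical-goal checks;
3. `03_score_pqm.py` — PQM scores and totals per strategy;
4. `04_compare_strategies.py` — paired tests and the robustness spread.

On the default cohort the hybrid presets score a higher total PQM than the
script presets at the easy and moderate settings (mean differences +17.3
and +8.0 points, paired tests p < 1e-12) and hold a smaller CI spread
across the three goal settings (0.053 vs 0.106) — better and more robust
plan quality, at the cost of nothing but the prediction step.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch — cohort simulation, metric
panel, PQM scoring, goal personalisation, paired comparisons, robustness
table — writing the result tables under `results/` and the JSON report to
the given path.
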