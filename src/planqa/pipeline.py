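"""End-to-end cohort pipeline: simulate -> evaluate -> score -> compare.

Deterministic for a fixed master seed: rerunning produces byte-identical
CSV outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence

import pandas as pd

from .goals import additional_goals, preset_goals, ring_goals, update_goals
from .grids import STRATEGY_LABELS
from .metrics import evaluate_goals, metric_table
from .phantom import STRATEGY_PRESETS, generate_cohort, predict_dose
from .pqm import score_table
from .stats import cohort_summary, compare_strategies, robustness_spread

#: Metrics carried into the statistical comparison (the evaluation panel).
COMPARISON_METRICS = [
    "bladder_D15", "bladder_D50",
    "femur_head_L_D25", "femur_head_L_D40",
    "femur_head_R_D25", "femur_head_R_D40",
    "PTV_D2", "PTV_D98", "CI", "HI",
]

#: Hybrid-vs-script pairs per goal setting, and automatic-vs-manual pairs.
DEFAULT_PAIRS = [
    ("script_easy", "hybrid_easy"),
    ("script_moderate", "hybrid_moderate"),
    ("script_hard", "hybrid_hard"),
    ("manual", "hybrid_moderate"),
    ("manual", "script_moderate"),
]


def personalized_goal_sets(structures, level: str, prescription: float = 5000.0,
                           with_ring: bool = False, with_additional: bool = False):
    """The hybrid goal workflow for one patient: preset -> predict -> update.

    Uses the hybrid preset for that level as the achievable-dose surrogate
    and returns (preset goal set, personalised goal set).
    """
    goal_set = preset_goals(level)
    if with_ring:
        goal_set.goals.extend(ring_goals(structures))
    if with_additional:
        goal_set.goals.extend(additional_goals())
    predicted = predict_dose(structures, STRATEGY_PRESETS[f"hybrid_{level}"], prescription)
    return goal_set, update_goals(goal_set, predicted, structures)


def run_cohort_analysis(
    n_patients: int = 20,
    master_seed: int = 1,
    strategy_labels: Sequence[str] = STRATEGY_LABELS,
    grid_shape=(80, 80, 80),
    spacing=(2.5, 2.5, 2.5),
    prescription: float = 5000.0,
    evaluate_goal_sets: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Run the full analysis on a synthetic cohort.

    Returns DataFrames: ``metrics`` (per-plan evaluation panel), ``pqm``
    (per-plan scores + totals), ``summary`` (mean +- sd per metric and
    strategy), ``comparisons`` (paired tests, including total PQM),
    ``robustness`` (spread across goal settings per method), and
    optionally ``goal_checks`` (per-plan pass rates of the personalised
    goal sets).
    """
    plans = generate_cohort(
        n_patients, strategy_labels, master_seed,
        grid_shape=grid_shape, spacing=spacing, prescription=prescription,
    )
    metrics = metric_table(plans)
    pqm = score_table(metrics)

    summary = cohort_summary(metrics, COMPARISON_METRICS)
    pairs = [(a, b) for a, b in DEFAULT_PAIRS
             if a in strategy_labels and b in strategy_labels]
    comparisons = compare_strategies(metrics, pairs, COMPARISON_METRICS)
    pqm_named = pqm.rename(columns={"total": "PQM_total"})
    comparisons = pd.concat(
        [comparisons, compare_strategies(pqm_named, pairs, ["PQM_total"])],
        ignore_index=True,
    )
    robustness = robustness_spread(summary)

    out = {
        "metrics": metrics,
        "pqm": pqm,
        "summary": summary,
        "comparisons": comparisons,
        "robustness": robustness,
    }

    if evaluate_goal_sets:
        rows = []
        by_patient = {}
        for plan in plans:
            by_patient.setdefault(plan.patient_id, []).append(plan)
        for patient_id, patient_plans in by_patient.items():
            structures = patient_plans[0].structures
            for level in ("easy", "moderate", "hard"):
                if f"hybrid_{level}" not in strategy_labels:
                    continue
                preset, personalised = personalized_goal_sets(structures, level, prescription)
                for plan in patient_plans:
                    goal_set = personalised if plan.strategy_label.startswith("hybrid") else preset
                    report = evaluate_goals(plan, goal_set)
                    evaluable = report[report["evaluable"]]
                    rows.append({
                        "patient_id": patient_id,
                        "strategy": plan.strategy_label,
                        "goal_level": level,
                        "goal_source": goal_set.level_label,
                        "n_goals": len(report),
                        "n_pass": int(evaluable["passed"].sum()),
                        "pass_rate": float(evaluable["passed"].mean()),
                    })
        out["goal_checks"] = pd.DataFrame(rows)

    return out


def write_outputs(results: Dict[str, pd.DataFrame], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, frame in results.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
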