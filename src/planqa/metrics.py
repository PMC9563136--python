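"""Plan-level indices: conformity, homogeneity, the evaluation panel, goal checks.

CI follows the Paddick form (TV_RI / TV) * (TV_RI / V_RI), with the
reference isodose defaulting to 95% of the prescription and V_RI counted
inside the body contour only.  HI is (D2 - D98) / prescription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import dvh
from .goals import ClinicalGoal, ClinicalGoalSet
from .grids import DoseGrid, Plan, check_congruent

#: (column name, structure, function) recipe for the per-plan metric panel.
PANEL_COLUMNS = [
    ("bladder_D15", "bladder", lambda d, m: dvh.dose_at_volume(d, m, 15)),
    ("bladder_D50", "bladder", lambda d, m: dvh.dose_at_volume(d, m, 50)),
    ("bladder_Dmean", "bladder", lambda d, m: dvh.mean_max_dose(d, m)[0]),
    ("bladder_Dmax", "bladder", lambda d, m: dvh.mean_max_dose(d, m)[1]),
    ("femur_head_L_D25", "femur_head_L", lambda d, m: dvh.dose_at_volume(d, m, 25)),
    ("femur_head_L_D40", "femur_head_L", lambda d, m: dvh.dose_at_volume(d, m, 40)),
    ("femur_head_L_Dmean", "femur_head_L", lambda d, m: dvh.mean_max_dose(d, m)[0]),
    ("femur_head_L_V10", "femur_head_L", lambda d, m: dvh.volume_at_dose(d, m, 1000)),
    ("femur_head_R_D25", "femur_head_R", lambda d, m: dvh.dose_at_volume(d, m, 25)),
    ("femur_head_R_D40", "femur_head_R", lambda d, m: dvh.dose_at_volume(d, m, 40)),
    ("femur_head_R_Dmean", "femur_head_R", lambda d, m: dvh.mean_max_dose(d, m)[0]),
    ("femur_head_R_V10", "femur_head_R", lambda d, m: dvh.volume_at_dose(d, m, 1000)),
    ("small_bowel_V45", "small_bowel", lambda d, m: dvh.volume_at_dose(d, m, 4500)),
    ("small_bowel_V15", "small_bowel", lambda d, m: dvh.volume_at_dose(d, m, 1500)),
    ("PTV_D2", "PTV", lambda d, m: dvh.dose_at_volume(d, m, 2)),
    ("PTV_D5", "PTV", lambda d, m: dvh.dose_at_volume(d, m, 5)),
    ("PTV_D95", "PTV", lambda d, m: dvh.dose_at_volume(d, m, 95)),
    ("PTV_D98", "PTV", lambda d, m: dvh.dose_at_volume(d, m, 98)),
    ("PTV_Dmax", "PTV", lambda d, m: dvh.mean_max_dose(d, m)[1]),
]


@dataclass(frozen=True)
class ConformityResult:
    """Voxel counts and the Paddick conformity index."""

    tv: int  # PTV volume, voxels
    v_ri: int  # reference-isodose volume (within body), voxels
    tv_ri: int  # PTV volume covered by the reference isodose, voxels
    ci: float
    undefined: bool = False  # v_ri == 0: ci reported as 0 with this flag


def conformity_index(
    dose: DoseGrid,
    ptv_mask: np.ndarray,
    reference_dose: float,
    body_mask: Optional[np.ndarray] = None,
) -> ConformityResult:
    """CI = (TV_RI / TV) * (TV_RI / V_RI) at the given reference isodose, cGy.

    V_RI is restricted to the body contour when a body mask is given; dose
    outside the patient is non-physical in the phantom model.
    """
    if reference_dose <= 0:
        raise ValueError("reference_dose must be positive")
    ptv_mask = check_congruent(dose, ptv_mask)
    tv = int(ptv_mask.sum())
    if tv == 0:
        raise ValueError("PTV mask is empty")
    hot = dose.values >= reference_dose
    if body_mask is not None:
        hot = hot & check_congruent(dose, body_mask)
    v_ri = int(hot.sum())
    tv_ri = int((hot & ptv_mask).sum())
    if v_ri == 0:
        return ConformityResult(tv=tv, v_ri=0, tv_ri=0, ci=0.0, undefined=True)
    ci = (tv_ri / tv) * (tv_ri / v_ri)
    return ConformityResult(tv=tv, v_ri=v_ri, tv_ri=tv_ri, ci=ci)


def homogeneity_index(d2: float, d98: float, prescription: float) -> float:
    """HI = (D2 - D98) / prescription; 0 is perfectly homogeneous."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    if d2 < d98:
        raise ValueError(f"D2 ({d2}) must be >= D98 ({d98})")
    return (d2 - d98) / prescription


def metric_panel(plan: Plan, reference_fraction: float = 0.95) -> Dict[str, float]:
    """Compute the full per-plan evaluation panel.

    ``reference_fraction`` sets the CI reference isodose as a fraction of
    the prescription (default 0.95 -> 4750 cGy at a 5000 cGy prescription;
    set 1.0 to use the prescription surface instead).  Missing structures
    yield NaN for their fields rather than aborting.
    """
    record: Dict[str, float] = {
        "patient_id": plan.patient_id,
        "strategy": plan.strategy_label,
    }
    for column, structure, fn in PANEL_COLUMNS:
        if structure in plan.structures and plan.structures[structure].any():
            record[column] = fn(plan.dose, plan.structures[structure])
        else:
            record[column] = math.nan
    body = plan.structures["body"] if "body" in plan.structures else None
    conf = conformity_index(
        plan.dose,
        plan.structures["PTV"],
        reference_dose=reference_fraction * plan.prescription,
        body_mask=body,
    )
    record["CI"] = conf.ci
    record["HI"] = homogeneity_index(record["PTV_D2"], record["PTV_D98"], plan.prescription)
    return record


def metric_table(plans: List[Plan], reference_fraction: float = 0.95) -> pd.DataFrame:
    """One metric_panel row per plan, as a DataFrame."""
    return pd.DataFrame([metric_panel(p, reference_fraction) for p in plans])


def _achieved(plan: Plan, goal: ClinicalGoal) -> float:
    mask = plan.structures[goal.structure]
    if goal.kind == "prescription_D95":
        return dvh.dose_at_volume(plan.dose, mask, 95)
    if goal.kind == "max_dose":
        return dvh.mean_max_dose(plan.dose, mask)[1]
    if goal.kind == "mean_dose":
        return dvh.mean_max_dose(plan.dose, mask)[0]
    if goal.kind == "dose_at_volume":
        return dvh.dose_at_volume(plan.dose, mask, goal.x_or_threshold)
    if goal.kind == "volume_at_dose":
        return dvh.volume_at_dose(plan.dose, mask, goal.x_or_threshold)
    raise ValueError(f"unknown goal kind {goal.kind!r}")


def evaluate_goals(plan: Plan, goals: ClinicalGoalSet) -> pd.DataFrame:
    """Evaluate each clinical goal against the plan.

    The prescription goal passes when PTV D95 >= its limit; every other
    goal is an upper bound and passes only when the achieved value is
    strictly below the limit (ties fail, matching "<" goals).  A goal on a
    structure the plan lacks is reported as unevaluable.
    """
    rows = []
    for goal in goals.goals:
        row = {
            "structure": goal.structure,
            "kind": goal.kind,
            "x_or_threshold": goal.x_or_threshold,
            "limit": goal.limit,
            "role": goal.role,
        }
        if goal.structure not in plan.structures or not plan.structures[goal.structure].any():
            row.update(achieved=math.nan, passed=False, evaluable=False)
        else:
            achieved = _achieved(plan, goal)
            if goal.kind == "prescription_D95":
                passed = achieved >= goal.limit
            else:
                passed = achieved < goal.limit
            row.update(achieved=achieved, passed=bool(passed), evaluable=True)
        rows.append(row)
    return pd.DataFrame(rows)
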