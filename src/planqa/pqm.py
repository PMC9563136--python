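"""Nine-metric plan-quality-metric (PQM) scoring.

Each metric is scored piecewise-linearly over a value window
[lower_limit, upper_limit] onto [min_score, max_score] points.  For
lower-is-better metrics the score is max_score at or below the lower
limit and min_score at or above the upper limit, linear in between;
orientation is reversed for higher-is-better metrics (CI is the only
one).  A plan's total is the sum of its nine per-metric scores, 0-90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional

import pandas as pd


@dataclass(frozen=True)
class PQMSpec:
    roi: str
    index: str
    metric_column: str  # column in the metric table holding the value
    lower_limit: float
    upper_limit: float
    min_score: float = 0.0
    max_score: float = 10.0
    orientation: Literal["lower_is_better", "higher_is_better"] = "lower_is_better"

    def __post_init__(self) -> None:
        if not self.lower_limit < self.upper_limit:
            raise ValueError("lower_limit must be < upper_limit")
        if not self.min_score < self.max_score:
            raise ValueError("min_score must be < max_score")


def default_pqm_specs() -> List[PQMSpec]:
    """The shipped nine-metric scoring table (all windows score 0-10 points).

    PTV D2 5250-5500 cGy, HI 0-0.15 and bladder D15 4000-5250, D50
    2500-4500 cGy, femoral-head D25 2000-3000 and D40 1250-2500 cGy are
    lower-is-better; CI 0.8-0.9 is the single higher-is-better metric.
    """
    rows = [
        ("PTV", "D2", "PTV_D2", 5250.0, 5500.0, "lower_is_better"),
        ("PTV", "HI", "HI", 0.0, 0.15, "lower_is_better"),
        ("PTV", "CI", "CI", 0.8, 0.9, "higher_is_better"),
        ("bladder", "D15", "bladder_D15", 4000.0, 5250.0, "lower_is_better"),
        ("bladder", "D50", "bladder_D50", 2500.0, 4500.0, "lower_is_better"),
        ("femur_head_L", "D25", "femur_head_L_D25", 2000.0, 3000.0, "lower_is_better"),
        ("femur_head_L", "D40", "femur_head_L_D40", 1250.0, 2500.0, "lower_is_better"),
        ("femur_head_R", "D25", "femur_head_R_D25", 2000.0, 3000.0, "lower_is_better"),
        ("femur_head_R", "D40", "femur_head_R_D40", 1250.0, 2500.0, "lower_is_better"),
    ]
    return [
        PQMSpec(roi, index, column, lo, hi, 0.0, 10.0, orientation)
        for roi, index, column, lo, hi, orientation in rows
    ]


def score_metric(value: float, spec: PQMSpec) -> float:
    """Score one metric value against its spec, clamped to [min_score, max_score]."""
    if not math.isfinite(value):
        raise ValueError(f"cannot score non-finite value for {spec.roi} {spec.index}")
    t = (value - spec.lower_limit) / (spec.upper_limit - spec.lower_limit)
    t = min(1.0, max(0.0, t))
    if spec.orientation == "lower_is_better":
        t = 1.0 - t
    return spec.min_score + t * (spec.max_score - spec.min_score)


@dataclass
class PQMReport:
    plan_key: Dict[str, object]
    scores: Dict[str, float]  # "<roi>_<index>" -> points
    total: Optional[float]  # None when any metric was unscorable
    unscored: List[str]


def score_plan(metrics: Dict[str, float], specs: Optional[List[PQMSpec]] = None) -> PQMReport:
    """Score one plan's metric record; the total is the sum of per-metric scores.

    ``metrics`` is a metric-table row (mapping column name to value).  A
    missing or non-finite metric is listed as unscored and voids the total
    (the plan is excluded from cohort totals with a warning downstream).
    """
    if specs is None:
        specs = default_pqm_specs()
    scores: Dict[str, float] = {}
    unscored: List[str] = []
    for spec in specs:
        key = f"{spec.roi}_{spec.index}"
        value = metrics.get(spec.metric_column, math.nan)
        if value is None or not math.isfinite(value):
            unscored.append(key)
        else:
            scores[key] = score_metric(float(value), spec)
    total = sum(scores.values()) if not unscored else None
    plan_key = {
        k: metrics[k] for k in ("patient_id", "strategy") if k in metrics
    }
    return PQMReport(plan_key=plan_key, scores=scores, total=total, unscored=unscored)


def score_table(metric_table: pd.DataFrame, specs: Optional[List[PQMSpec]] = None) -> pd.DataFrame:
    """Score every row of a metric table; returns per-metric scores plus the total."""
    if specs is None:
        specs = default_pqm_specs()
    rows = []
    for _, record in metric_table.iterrows():
        report = score_plan(record.to_dict(), specs)
        row = dict(report.plan_key)
        row.update({f"score_{k}": round(v, 2) for k, v in report.scores.items()})
        row["total"] = round(report.total, 2) if report.total is not None else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
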