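"""Clinical goals: presets, prediction-driven goal updating, ring and extra goals.

A clinical goal is a dose-volume requirement with a structure, a kind
(prescription coverage, max/mean dose, Dx or Vx limit), a limit, and a
role.  The hybrid workflow replaces each organ-at-risk goal's limit with
the same index read off a predicted achievable dose, leaving target goals
untouched — personalisation may loosen a goal as well as tighten it (a
bladder largely overlapping the PTV cannot meet a population-level limit).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Literal, Optional

import numpy as np
from scipy import ndimage

from . import dvh
from .grids import DoseGrid, StructureSet

GoalKind = Literal[
    "prescription_D95", "max_dose", "mean_dose", "dose_at_volume", "volume_at_dose"
]
GoalRole = Literal["target", "oar", "auxiliary"]

#: Table of goal-preset limits per level, cGy.
PRESET_LIMITS = {
    # level: (PTV max, bladder mean, femur mean each side)
    "moderate": (5250.0, 4000.0, 1800.0),
    "hard": (5100.0, 2000.0, 900.0),
    "easy": (5500.0, 4500.0, 2700.0),
}

RING_5MM_NAME = "ring_ptv_5mm"
RING_15MM_NAME = "ring_ptv_15mm"


@dataclass
class ClinicalGoal:
    structure: str
    kind: GoalKind
    limit: float  # cGy for dose goals, percent for volume_at_dose
    x_or_threshold: float = 0.0  # percent for dose_at_volume, cGy for volume_at_dose
    role: GoalRole = "oar"

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("goal limit must be positive")


@dataclass
class ClinicalGoalSet:
    goals: List[ClinicalGoal]
    level_label: str = "custom"

    def __post_init__(self) -> None:
        n_rx = sum(1 for g in self.goals if g.kind == "prescription_D95")
        if n_rx != 1:
            raise ValueError(f"goal set must contain exactly one prescription goal, got {n_rx}")
        keys = [(g.structure, g.kind, g.x_or_threshold) for g in self.goals]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (structure, kind, x_or_threshold) goal entries")

    def to_json(self) -> str:
        return json.dumps(
            {"level_label": self.level_label, "goals": [asdict(g) for g in self.goals]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClinicalGoalSet":
        payload = json.loads(text)
        return cls(
            goals=[ClinicalGoal(**g) for g in payload["goals"]],
            level_label=payload.get("level_label", "custom"),
        )


def preset_goals(level: str) -> ClinicalGoalSet:
    """The three shipped goal-setting levels (easy / moderate / hard).

    Every level prescribes D95 = 5000 cGy to the PTV; the levels differ in
    the PTV max-dose cap and in the bladder / femoral-head mean-dose limits.
    """
    if level not in PRESET_LIMITS:
        raise ValueError(f"unknown level {level!r}; valid: {sorted(PRESET_LIMITS)}")
    ptv_max, bladder_mean, femur_mean = PRESET_LIMITS[level]
    goals = [
        ClinicalGoal("PTV", "prescription_D95", limit=5000.0, role="target"),
        ClinicalGoal("PTV", "max_dose", limit=ptv_max, role="target"),
        ClinicalGoal("bladder", "mean_dose", limit=bladder_mean, role="oar"),
        ClinicalGoal("femur_head_L", "mean_dose", limit=femur_mean, role="oar"),
        ClinicalGoal("femur_head_R", "mean_dose", limit=femur_mean, role="oar"),
    ]
    return ClinicalGoalSet(goals=goals, level_label=level)


def _predicted_index(goal: ClinicalGoal, predicted: DoseGrid, mask: np.ndarray) -> float:
    if goal.kind == "max_dose":
        return dvh.mean_max_dose(predicted, mask)[1]
    if goal.kind == "mean_dose":
        return dvh.mean_max_dose(predicted, mask)[0]
    if goal.kind == "dose_at_volume":
        return dvh.dose_at_volume(predicted, mask, goal.x_or_threshold)
    if goal.kind == "volume_at_dose":
        return dvh.volume_at_dose(predicted, mask, goal.x_or_threshold)
    raise ValueError(f"cannot personalise goal of kind {goal.kind!r}")


def update_goals(
    goals: ClinicalGoalSet,
    predicted: DoseGrid,
    structures: StructureSet,
    mode: Literal["replace", "tighten_only"] = "replace",
) -> ClinicalGoalSet:
    """Personalise OAR goals from a predicted achievable dose.

    Each OAR-role goal's limit becomes the same dose-volume index evaluated
    on the predicted dose (``replace``, the default, is unconditional and
    may loosen a goal; ``tighten_only`` keeps the stricter of old and
    predicted).  Target and auxiliary goals are returned unchanged; goal
    count, order, structures, kinds and roles are all preserved.  A goal on
    a structure absent from the prediction is kept unchanged.
    """
    if predicted.values.shape != structures.shape:
        raise ValueError("predicted dose and structures are not congruent")
    updated: List[ClinicalGoal] = []
    for goal in goals.goals:
        goal = copy.copy(goal)
        if goal.role == "oar" and goal.structure in structures and structures[goal.structure].any():
            predicted_value = _predicted_index(goal, predicted, structures[goal.structure])
            if predicted_value > 0 and (mode == "replace" or predicted_value < goal.limit):
                goal.limit = float(predicted_value)
        updated.append(goal)
    return ClinicalGoalSet(goals=updated, level_label="custom")


def expand_mask(mask: np.ndarray, margin: float, spacing) -> np.ndarray:
    """Isotropic 3-D margin expansion by Euclidean distance between voxel centers.

    A voxel belongs to the expansion iff its center lies within ``margin``
    mm of some original voxel center (distance-transform dilation).
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if margin == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin


def ring_goals(structures: StructureSet) -> List[ClinicalGoal]:
    """Auxiliary conformity rings: body minus (PTV + 5 mm) and minus (PTV + 15 mm).

    Registers the two derived ring structures on the structure set and
    returns max-dose goals of 4200 and 3000 cGy on them.  An expansion that
    swallows the whole body leaves an empty ring, which goal evaluation
    reports as unevaluable.
    """
    for required in ("body", "PTV"):
        if required not in structures:
            raise ValueError(f"ring goals require structure {required!r}")
    body = structures["body"]
    ptv = structures["PTV"]
    goals = []
    for name, margin, limit in ((RING_5MM_NAME, 5.0, 4200.0), (RING_15MM_NAME, 15.0, 3000.0)):
        ring = body & ~expand_mask(ptv, margin, structures.spacing)
        structures.add(name, ring)
        goals.append(ClinicalGoal(name, "max_dose", limit=limit, role="auxiliary"))
    return goals


def additional_goals() -> List[ClinicalGoal]:
    """Extra organ-at-risk goals beyond the level presets.

    Small bowel V45Gy < 5% and V15Gy < 30%; femoral heads V10Gy < 75%
    (both sides); bladder max dose < 5250 cGy.
    """
    return [
        ClinicalGoal("small_bowel", "volume_at_dose", limit=5.0, x_or_threshold=4500.0),
        ClinicalGoal("small_bowel", "volume_at_dose", limit=30.0, x_or_threshold=1500.0),
        ClinicalGoal("femur_head_L", "volume_at_dose", limit=75.0, x_or_threshold=1000.0),
        ClinicalGoal("femur_head_R", "volume_at_dose", limit=75.0, x_or_threshold=1000.0),
        ClinicalGoal("bladder", "max_dose", limit=5250.0),
    ]
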