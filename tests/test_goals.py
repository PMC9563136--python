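"""Goal presets, prediction-driven goal updates, margin expansion, ring/extra goals."""

import itertools

import numpy as np
import pytest

from planqa import (
    ClinicalGoalSet,
    StrategyParams,
    additional_goals,
    evaluate_goals,
    expand_mask,
    predict_dose,
    preset_goals,
    ring_goals,
    update_goals,
)
from planqa.dvh import mean_max_dose
from planqa.goals import RING_15MM_NAME, RING_5MM_NAME, ClinicalGoal
from planqa.grids import DoseGrid, Plan
from planqa.phantom import STRATEGY_PRESETS, generate_phantom


class TestPresetGoals:
    @pytest.mark.parametrize(
        "level,ptv_max,bladder_mean,femur_mean",
        [("moderate", 5250, 4000, 1800), ("hard", 5100, 2000, 900), ("easy", 5500, 4500, 2700)],
    )
    def test_levels(self, level, ptv_max, bladder_mean, femur_mean):
        gs = preset_goals(level)
        by = {(g.structure, g.kind): g.limit for g in gs.goals}
        assert by[("PTV", "prescription_D95")] == 5000.0
        assert by[("PTV", "max_dose")] == ptv_max
        assert by[("bladder", "mean_dose")] == bladder_mean
        assert by[("femur_head_L", "mean_dose")] == femur_mean
        assert by[("femur_head_R", "mean_dose")] == femur_mean

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            preset_goals("impossible")

    def test_goal_set_validation(self):
        with pytest.raises(ValueError, match="prescription"):
            ClinicalGoalSet(goals=[ClinicalGoal("bladder", "mean_dose", limit=4000.0)])

    def test_json_round_trip(self):
        gs = preset_goals("moderate")
        again = ClinicalGoalSet.from_json(gs.to_json())
        assert again.level_label == "moderate"
        assert [g.__dict__ for g in again.goals] == [g.__dict__ for g in gs.goals]


@pytest.fixture(scope="module")
def predicted_setup():
    structures = generate_phantom(seed=5)
    predicted = predict_dose(structures, STRATEGY_PRESETS["hybrid_moderate"])
    return structures, predicted


class TestUpdateGoals:
    def test_oar_limits_replaced_with_predicted_indices(self, predicted_setup):
        structures, predicted = predicted_setup
        updated = update_goals(preset_goals("easy"), predicted, structures)
        for goal in updated.goals:
            if goal.role == "oar":
                mean, peak = mean_max_dose(predicted, structures[goal.structure])
                expected = mean if goal.kind == "mean_dose" else peak
                assert goal.limit == expected
        assert updated.level_label == "custom"

    def test_replacement_may_loosen(self, predicted_setup):
        structures, predicted = predicted_setup
        updated = update_goals(preset_goals("hard"), predicted, structures)
        bladder = next(g for g in updated.goals if g.structure == "bladder")
        predicted_mean = mean_max_dose(predicted, structures["bladder"])[0]
        assert predicted_mean > 2000.0  # hard preset is infeasible here
        assert bladder.limit == predicted_mean  # loosened, not clamped

    def test_tighten_only_mode_never_loosens(self, predicted_setup):
        structures, predicted = predicted_setup
        updated = update_goals(preset_goals("hard"), predicted, structures, mode="tighten_only")
        original = {(g.structure, g.kind): g.limit for g in preset_goals("hard").goals}
        for goal in updated.goals:
            assert goal.limit <= original[(goal.structure, goal.kind)]

    def test_targets_and_structure_untouched(self, predicted_setup):
        structures, predicted = predicted_setup
        goals = preset_goals("moderate")
        updated = update_goals(goals, predicted, structures)
        assert len(updated.goals) == len(goals.goals)
        for before, after in zip(goals.goals, updated.goals):
            assert (before.structure, before.kind, before.role) == (
                after.structure, after.kind, after.role,
            )
            if before.role == "target":
                assert after.limit == before.limit

    def test_idempotent(self, predicted_setup):
        structures, predicted = predicted_setup
        once = update_goals(preset_goals("easy"), predicted, structures)
        twice = update_goals(once, predicted, structures)
        assert [g.limit for g in once.goals] == [g.limit for g in twice.goals]

    def test_absent_structure_kept_unchanged(self, predicted_setup):
        structures, predicted = predicted_setup
        goals = ClinicalGoalSet(goals=[
            ClinicalGoal("PTV", "prescription_D95", limit=5000.0, role="target"),
            ClinicalGoal("rectum", "mean_dose", limit=3000.0),
        ])
        updated = update_goals(goals, predicted, structures)
        assert updated.goals[1].limit == 3000.0


def ball_oracle(mask, margin, spacing):
    """Exhaustive voxel-center Euclidean-ball membership."""
    out = np.zeros_like(mask)
    sources = np.argwhere(mask)
    for idx in np.ndindex(mask.shape):
        pos = np.array(idx) * spacing
        for src in sources:
            if np.linalg.norm(pos - src * spacing) <= margin:
                out[idx] = True
                break
    return out


class TestExpandMask:
    spacing = np.array([2.5, 2.5, 2.5])

    def test_zero_margin_identity(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[3, 3, 3] = True
        assert np.array_equal(expand_mask(mask, 0.0, self.spacing), mask)

    @pytest.mark.parametrize("margin", [5.0, 15.0])
    def test_single_voxel_ball(self, margin):
        n = 15
        mask = np.zeros((n, n, n), dtype=bool)
        mask[7, 7, 7] = True
        got = expand_mask(mask, margin, self.spacing)
        assert np.array_equal(got, ball_oracle(mask, margin, self.spacing))

    def test_random_masks_match_oracle(self):
        rng = np.random.default_rng(42)
        for margin in (5.0, 15.0):
            mask = rng.random((9, 9, 9)) < 0.05
            mask[4, 4, 4] = True
            got = expand_mask(mask, margin, self.spacing)
            assert np.array_equal(got, ball_oracle(mask, margin, self.spacing))

    def test_monotone_in_margin(self, phantom):
        m5 = expand_mask(phantom["PTV"], 5.0, phantom.spacing)
        m15 = expand_mask(phantom["PTV"], 15.0, phantom.spacing)
        assert np.all(m15[m5])  # 15 mm expansion strictly contains 5 mm
        assert m15.sum() > m5.sum()

    def test_negative_margin_raises(self):
        with pytest.raises(ValueError):
            expand_mask(np.ones((3, 3, 3), dtype=bool), -1.0, self.spacing)


class TestRingAndAdditionalGoals:
    def test_ring_goal_limits_and_roles(self):
        structures = generate_phantom(seed=2)
        goals = ring_goals(structures)
        assert sorted(g.limit for g in goals) == [3000.0, 4200.0]
        assert all(g.role == "auxiliary" and g.kind == "max_dose" for g in goals)

    def test_ring_masks_set_algebra(self):
        structures = generate_phantom(seed=2)
        ring_goals(structures)
        ptv, body = structures["PTV"], structures["body"]
        for name, margin in ((RING_5MM_NAME, 5.0), (RING_15MM_NAME, 15.0)):
            ring = structures[name]
            assert not np.any(ring & ptv)
            expected = body & ~expand_mask(ptv, margin, structures.spacing)
            assert np.array_equal(ring, expected)
        assert np.all(structures[RING_5MM_NAME][structures[RING_15MM_NAME]])

    def test_additional_goals_contract(self, zero_oar_plan):
        goals = additional_goals()
        assert len(goals) == 5
        bladder_max = next(g for g in goals if g.structure == "bladder")
        assert bladder_max.kind == "max_dose" and bladder_max.limit == 5250.0
        vx = {(g.structure, g.x_or_threshold): g.limit for g in goals if g.kind == "volume_at_dose"}
        assert vx[("small_bowel", 4500.0)] == 5.0
        assert vx[("small_bowel", 1500.0)] == 30.0
        assert vx[("femur_head_L", 1000.0)] == 75.0
        assert vx[("femur_head_R", 1000.0)] == 75.0
        # on a zero-dose-OAR plan every additional goal passes
        gs = ClinicalGoalSet(
            goals=[ClinicalGoal("PTV", "prescription_D95", limit=5000.0, role="target")]
            + goals
        )
        report = evaluate_goals(zero_oar_plan, gs)
        assert report["passed"].all()
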