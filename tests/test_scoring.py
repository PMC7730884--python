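"""Load profiles from the lab impulse table, daily scoring, and goal evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jolo.labels import UNKNOWN
from jolo.scoring import (
    Goal,
    assign_profile,
    build_profiles,
    evaluate_goals,
    load_impulse_table,
    score_day,
)

# Published point weights per cycle, rounded to 2 decimals: (activity, joint)
# -> (no-OA, HipOA, KneeOA). Derived by normalizing each lab impulse to the
# control walking impulse of the same joint.
EXPECTED_POINTS = {
    ("walking", "hip"): (1.00, 0.91, 0.95),
    ("walking", "knee"): (1.00, 0.94, 1.00),
    ("ascending_stairs", "hip"): (1.11, 1.21, 1.42),
    ("ascending_stairs", "knee"): (1.63, 1.67, 1.72),
    ("descending_stairs", "hip"): (1.12, 1.16, 1.51),
    ("descending_stairs", "knee"): (1.55, 1.60, 1.71),
    ("sit_down", "hip"): (0.71, 0.69, 0.80),
    ("sit_down", "knee"): (1.77, 1.71, 1.66),
    ("stand_up", "hip"): (0.65, 0.58, 0.67),
    ("stand_up", "knee"): (1.57, 1.42, 1.42),
}


class TestBuildProfiles:
    def test_all_thirty_point_cells_reproduced(self):
        profiles = build_profiles()
        for (activity, joint), expected in EXPECTED_POINTS.items():
            for profile_name, value in zip(("no-OA", "HipOA", "KneeOA"), expected):
                got = profiles[profile_name].display_points()[(activity, joint)]
                assert got == pytest.approx(value, abs=1e-9), (activity, joint, profile_name)

    def test_healthy_walking_is_the_unit(self):
        prof = build_profiles()["no-OA"]
        assert prof.points[("walking", "hip")] == 1.0
        assert prof.points[("walking", "knee")] == 1.0

    def test_scale_invariance(self):
        tbl = load_impulse_table()
        doubled = tbl.assign(impulse=tbl["impulse"] * 2)
        a = build_profiles(tbl)["KneeOA"].points
        b = build_profiles(doubled)["KneeOA"].points
        assert a == b

    def test_incomplete_table_rejected(self):
        tbl = load_impulse_table().iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            build_profiles(tbl)


class TestScoreDay:
    def test_ten_thousand_steps_is_one_hundred_points(self):
        status = score_day({"walking": 10000}, build_profiles()["KneeOA"], "knee")
        assert status.points_earned == pytest.approx(100.0)
        assert status.fraction == pytest.approx(1.0)

    def test_stair_cycles_weighted(self):
        status = score_day({"ascending_stairs": 1000}, build_profiles()["KneeOA"], "knee")
        assert status.points_earned == pytest.approx(17.2, abs=0.01)

    def test_untemplated_labels_earn_nothing(self):
        status = score_day(
            {"jogging": 5000, "cycling": 5000, UNKNOWN: 100, "sitting_or_standing": 100},
            build_profiles()["no-OA"], "hip",
        )
        assert status.points_earned == 0.0

    def test_transition_labels_map_to_templates(self):
        prof = build_profiles()["HipOA"]
        status = score_day({"sit_to_stand": 100, "stand_to_sit": 100}, prof, "hip")
        # standing up uses the stand-up template (0.58), sitting down sit-down (0.69)
        assert status.points_earned == pytest.approx((100 * 0.58 + 100 * 0.69) / 100, abs=0.01)

    def test_unknown_joint_rejected(self):
        with pytest.raises(ValueError, match="joint"):
            score_day({"walking": 1}, build_profiles()["no-OA"], "shoulder")

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 20000), st.integers(0, 2000), st.integers(1, 10))
    def test_linear_and_monotone(self, walk, stairs, k):
        prof = build_profiles()["KneeOA"]
        base = score_day({"walking": walk, "ascending_stairs": stairs}, prof, "knee")
        scaled = score_day({"walking": k * walk, "ascending_stairs": k * stairs}, prof, "knee")
        assert scaled.points_earned == pytest.approx(k * base.points_earned, rel=1e-12, abs=1e-12)
        more = score_day({"walking": walk + 1, "ascending_stairs": stairs}, prof, "knee")
        assert more.points_earned >= base.points_earned


class TestAssignProfile:
    def test_diagnosis_maps_to_profile_and_joint(self):
        prof, joints = assign_profile("KneeOA")
        assert prof.name == "KneeOA" and joints == ("knee",)
        prof, joints = assign_profile("HipOA")
        assert prof.name == "HipOA" and joints == ("hip",)
        prof, joints = assign_profile("no-OA")
        assert joints == ("hip", "knee")

    def test_unknown_diagnosis_rejected(self):
        with pytest.raises(ValueError, match="diagnosis"):
            assign_profile("shoulder")


def day_of(activity, seconds, total=7200):
    labels = np.full(total, "sitting_or_standing", dtype=object)
    labels[:seconds] = activity
    return labels


class TestEvaluateGoals:
    def test_weekly_cycling_goal_achieved(self):
        goal = Goal("cycling", 30, 5)
        days = {f"d{i}": day_of("cycling", 1800) for i in range(5)}
        (progress,) = evaluate_goals(days, [goal])
        assert progress.sessions == 5 and progress.achieved

    def test_block_just_under_ten_minutes_does_not_count(self):
        (progress,) = evaluate_goals({"d0": day_of("walking", 599)}, [Goal("walking", 5, 1)])
        assert progress.qualifying_minutes_per_day["d0"] == 0.0
        assert not progress.achieved

    def test_blocks_accumulate_within_a_day(self):
        labels = np.full(5000, "sitting_or_standing", dtype=object)
        for start in (0, 1500, 3000):  # three separated 12 min walking blocks
            labels[start : start + 720] = "walking"
        (progress,) = evaluate_goals({"d0": labels}, [Goal("walking", 30, 1)])
        assert progress.qualifying_minutes_per_day["d0"] == pytest.approx(36.0)
        assert progress.achieved

    def test_short_unknown_gap_does_not_break_a_block(self):
        labels = np.full(1300, "sitting_or_standing", dtype=object)
        labels[:300] = "cycling"
        labels[300:303] = UNKNOWN  # 3 s dropout inside the bout
        labels[303:903] = "cycling"
        (progress,) = evaluate_goals({"d0": labels}, [Goal("cycling", 15, 1)])
        assert progress.qualifying_minutes_per_day["d0"] == pytest.approx(900 / 60)

    def test_long_gap_breaks_the_block(self):
        labels = np.full(1500, "sitting_or_standing", dtype=object)
        labels[:300] = "cycling"
        labels[300:330] = UNKNOWN  # 30 s dropout: two sub-10-min fragments
        labels[330:930] = "cycling"
        (progress,) = evaluate_goals({"d0": labels}, [Goal("cycling", 10, 1)])
        assert progress.qualifying_minutes_per_day["d0"] == pytest.approx(10.0)

    def test_order_of_days_irrelevant(self):
        goal = Goal("walking", 20, 3)
        days = {f"d{i}": day_of("walking", 600 + 300 * i) for i in range(4)}
        forward = evaluate_goals(days, [goal])[0]
        backward = evaluate_goals(dict(reversed(list(days.items()))), [goal])[0]
        assert forward.sessions == backward.sessions == sum(
            1 for m in forward.qualifying_minutes_per_day.values() if m >= 20
        )
        assert forward.achieved == backward.achieved

    def test_empty_week_rejected(self):
        with pytest.raises(ValueError, match="one day"):
            evaluate_goals({}, [Goal("walking", 10, 1)])
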