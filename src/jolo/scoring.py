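"""Joint-load point profiles, daily functional-status scoring, and goal evaluation.

Joint contact force impulses — the time integral of the body-weight-normalized
resultant contact force over one movement cycle, in (N/BW)*s — were measured in
a motion-capture lab for five template activities (level walking, ascending and
descending stairs, sitting down, standing up), two joints (hip, knee) and three
populations (healthy controls, end-stage hip OA, end-stage knee OA). Dividing
each impulse by the control walking impulse of the same joint turns the table
into dimensionless point weights per cycle: level walking earns 1 point per
stride per joint in the healthy profile, heavier activities earn more (e.g.
1.72 knee points per ascended stair for the knee-OA profile).

A day's functional status is the weighted cycle sum divided by 100, so that
10,000 walking strides at weight 1 score exactly 100 points — the standard
daily target, which a therapist may override per patient. Jogging and cycling
have no lab impulse templates; they carry zero load points (configurable) but
count fully toward activity-minute goals.

Activity goals (duration per session x sessions per week) only credit time
accumulated in blocks of at least 10 minutes; isolated short bouts do not
count. Within a block, up to 5 s of contiguous ``unknown`` seconds are
tolerated so one misclassified second does not void a bout.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from jolo.labels import UNKNOWN
from jolo.postprocess import CycleCounts

logger = logging.getLogger(__name__)

TEMPLATE_ACTIVITIES = ("walking", "ascending_stairs", "descending_stairs", "sit_down", "stand_up")
JOINTS = ("hip", "knee")
POPULATIONS = ("Controls", "HipOA", "KneeOA")
#: population token -> profile name
PROFILE_NAMES = {"Controls": "no-OA", "HipOA": "HipOA", "KneeOA": "KneeOA"}
#: classifier labels -> impulse-table template activities
LABEL_TO_TEMPLATE = {
    "walking": "walking",
    "ascending_stairs": "ascending_stairs",
    "descending_stairs": "descending_stairs",
    "stand_to_sit": "sit_down",
    "sit_to_stand": "stand_up",
}
POINTS_PER_TARGET_UNIT = 100.0  # 10,000 walking strides at weight 1 == 100 points
DEFAULT_POINT_TARGET = 100.0
GOAL_BLOCK_MIN_S = 600
GOAL_GAP_TOLERANCE_S = 5


def load_impulse_table(path: str | None = None) -> pd.DataFrame:
    """The packaged lab impulse table: activity, joint, population, impulse.

    Raises if any cell of the 5 x 2 x 3 grid is missing or non-positive.
    """
    if path is None:
        ref = importlib.resources.files("jolo.data").joinpath("impulse_table.csv")
        with importlib.resources.as_file(ref) as p:
            tbl = pd.read_csv(p)
    else:
        tbl = pd.read_csv(path)
    _validate_table(tbl)
    return tbl


def _validate_table(tbl: pd.DataFrame) -> None:
    expected = {(a, j, p) for a in TEMPLATE_ACTIVITIES for j in JOINTS for p in POPULATIONS}
    got = set(zip(tbl["activity"], tbl["joint"], tbl["population"]))
    missing = expected - got
    if missing:
        raise ValueError(f"impulse table incomplete; missing cells {sorted(missing)[:3]}...")
    if (tbl["impulse"] <= 0).any():
        raise ValueError("impulses must be positive")


@dataclass
class LoadProfile:
    """Per-activity, per-joint point weights per cycle for one population profile.

    ``points[(activity, joint)]`` is kept at full precision;
    :meth:`display_points` rounds to the 2 decimals used for reporting.
    """

    name: str
    points: dict[tuple[str, str], float]

    def display_points(self) -> dict[tuple[str, str], float]:
        return {k: round(v, 2) for k, v in self.points.items()}

    def weight(self, label: str, joint: str) -> float:
        """Point weight for a classifier label (0 for activities without a template).

        Weights are the published 2-decimal values — the point system patients
        and therapists see — so e.g. 10,000 walking strides score exactly
        100 points in every profile.
        """
        template = LABEL_TO_TEMPLATE.get(label)
        if template is None:
            return 0.0
        return round(self.points[(template, joint)], 2)


def build_profiles(tbl: pd.DataFrame | None = None) -> dict[str, LoadProfile]:
    """Normalize impulses to healthy walking per joint, giving the three profiles.

    points[(a, j)] for profile P = impulse[(a, j, P)] / impulse[(walking, j, Controls)].
    Scale-invariant in the table's units.
    """
    if tbl is None:
        tbl = load_impulse_table()
    else:
        _validate_table(tbl)
    lut = {(r.activity, r.joint, r.population): float(r.impulse) for r in tbl.itertuples()}
    reference = {j: lut[("walking", j, "Controls")] for j in JOINTS}
    profiles = {}
    for pop in POPULATIONS:
        points = {
            (a, j): lut[(a, j, pop)] / reference[j]
            for a in TEMPLATE_ACTIVITIES
            for j in JOINTS
        }
        profiles[PROFILE_NAMES[pop]] = LoadProfile(PROFILE_NAMES[pop], points)
    return profiles


@dataclass
class FunctionalStatus:
    """A day's joint-load score in points, against a (possibly personalized) target."""

    points_earned: float
    point_target: float
    joint: str
    profile: str
    breakdown: dict[str, float] = field(default_factory=dict)
    """Points contributed per activity label."""

    @property
    def fraction(self) -> float:
        return self.points_earned / self.point_target


def score_day(
    counts: CycleCounts | Mapping[str, float],
    profile: LoadProfile,
    joint: str,
    point_target: float = DEFAULT_POINT_TARGET,
) -> FunctionalStatus:
    """Score a day of cycle counts in joint-load points.

    points = sum over activities of cycles x weight(activity, joint) / 100;
    the divisor fixes the scale so 10,000 walking strides at weight 1 yield
    100 points. Labels without an impulse template (jogging, cycling,
    ``unknown``, ``sitting_or_standing``) earn zero.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    if point_target <= 0:
        raise ValueError("point_target must be positive")
    cycles = counts.cycles if isinstance(counts, CycleCounts) else dict(counts)
    breakdown = {}
    for label, n in cycles.items():
        if n < 0:
            raise ValueError(f"negative cycle count for {label!r}")
        pts = n * profile.weight(label, joint) / POINTS_PER_TARGET_UNIT
        if pts:
            breakdown[label] = pts
    return FunctionalStatus(
        points_earned=float(sum(breakdown.values())),
        point_target=float(point_target),
        joint=joint,
        profile=profile.name,
        breakdown=breakdown,
    )


def assign_profile(diagnosis: str) -> tuple[LoadProfile, tuple[str, ...]]:
    """Map a diagnosis token to its load profile and the joint(s) to report.

    "HipOA" -> hip, "KneeOA" -> knee, "no-OA" -> both joints.
    """
    canonical = {"no-oa": "no-OA", "hipoa": "HipOA", "kneeoa": "KneeOA"}
    key = canonical.get(diagnosis.replace("_", "-").lower())
    if key is None:
        raise ValueError(f"unknown diagnosis {diagnosis!r}; expected no-OA, HipOA or KneeOA")
    profile = build_profiles()[key]
    joints = {"no-OA": ("hip", "knee"), "HipOA": ("hip",), "KneeOA": ("knee",)}[key]
    return profile, joints


@dataclass(frozen=True)
class Goal:
    """An activity goal: duration per session (minutes) x sessions per week."""

    activity: str
    duration_min: float
    frequency_per_week: int

    def __post_init__(self) -> None:
        if self.duration_min <= 0 or self.frequency_per_week < 1:
            raise ValueError("duration_min must be positive and frequency_per_week >= 1")


@dataclass
class GoalProgress:
    goal: Goal
    qualifying_minutes_per_day: dict[str, float]
    sessions: int
    achieved: bool


def _qualifying_seconds(labels: np.ndarray, activity: str) -> float:
    """Activity seconds inside blocks of >= 10 min, tolerating short unknown gaps.

    Runs of the activity separated by at most GOAL_GAP_TOLERANCE_S seconds of
    ``unknown`` merge into one block; a block qualifies when the activity time
    in it reaches GOAL_BLOCK_MIN_S, and only the activity seconds (not the
    tolerated gaps) are credited.
    """
    is_act = labels == activity
    is_gap = labels == UNKNOWN
    total = 0.0
    i, n = 0, len(labels)
    while i < n:
        if not is_act[i]:
            i += 1
            continue
        block = 0
        j = i
        while j < n:
            if is_act[j]:
                block += 1
                j += 1
            elif is_gap[j]:
                g = 0
                while j + g < n and is_gap[j + g]:
                    g += 1
                if g <= GOAL_GAP_TOLERANCE_S and j + g < n and is_act[j + g]:
                    j += g
                else:
                    break
            else:
                break
        if block >= GOAL_BLOCK_MIN_S:
            total += block
        i = j
    return total


def evaluate_goals(
    labels_by_day: Mapping[str, pd.Series | np.ndarray],
    goals: Sequence[Goal],
) -> list[GoalProgress]:
    """Progress of each goal over one week of per-second label streams.

    A day counts as a session for a goal when its qualifying minutes (summed
    over all >= 10 min blocks of the goal's activity) reach the goal duration;
    the goal is achieved when the session count reaches the weekly frequency.
    Invariant to the order of days.
    """
    if not labels_by_day:
        raise ValueError("need at least one day of labels")
    out = []
    for goal in goals:
        per_day = {}
        for day, labels in labels_by_day.items():
            arr = labels.to_numpy(dtype=object) if isinstance(labels, pd.Series) else np.asarray(labels, dtype=object)
            per_day[day] = _qualifying_seconds(arr, goal.activity) / 60.0
        sessions = sum(1 for m in per_day.values() if m >= goal.duration_min)
        out.append(
            GoalProgress(
                goal=goal,
                qualifying_minutes_per_day=per_day,
                sessions=sessions,
                achieved=sessions >= goal.frequency_per_week,
            )
        )
    return out
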