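"""Synthetic accelerometer data with known ground truth.

Emulates hip-worn 50 Hz tri-axial recordings of the seven target activities plus
phone-at-rest periods. Locomotor classes are quasi-periodic: a fundamental at
the activity's cadence plus two harmonics, with class-specific amplitude,
harmonic mix and per-axis weighting so that classes are separable but not
trivially identical. Sit/stand transitions are single smoothed transients (one
per second of the bout) whose time asymmetry distinguishes rising from sitting
down. Gravity (9.81 m/s^2) sits on the first pre-orientation axis; each subject
gets a random orientation (axis sign flips plus a small rotation) to exercise
the rectification step. Everything is deterministic given a seed.

The default per-activity durations scale the training-data mix of the source
study (walking-dominated, scarce stair and transition data) down to desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from jolo.labels import ACTIVITIES, CYCLIC_ACTIVITIES, SITTING_OR_STANDING, TRANSITION_ACTIVITIES
from jolo.signal_io import DEFAULT_SAMPLE_RATE, Recording

GRAVITY = 9.81


@dataclass
class ActivitySpec:
    """Signal model parameters for one activity.

    cadence is in cycles/s (0 for stationary and transitions), amplitude and
    noise_sd in m/s^2. harmonics are relative weights of the fundamental and
    overtones; axis_weights spread the amplitude over the (vertical, AP, ML)
    pre-orientation axes. rise_exponent shapes the transient for transitions
    (< 1: fast rise / slow fall, > 1: slow rise / fast fall). orientation is an
    optional 3x3 matrix applied to the signal before output.
    """

    activity: str
    cadence: float = 0.0
    amplitude: float = 0.0
    noise_sd: float = 0.05
    harmonics: tuple[float, ...] = (1.0,)
    axis_weights: tuple[float, float, float] = (1.0, 0.4, 0.2)
    rise_exponent: float = 1.0
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cadence < 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("cadence, amplitude and noise_sd must be non-negative")


DEFAULT_SPECS: dict[str, ActivitySpec] = {
    "walking": ActivitySpec("walking", cadence=1.9, amplitude=2.5, noise_sd=0.30,
                            harmonics=(1.0, 0.45, 0.20), axis_weights=(0.9, 0.5, 0.3)),
    "ascending_stairs": ActivitySpec("ascending_stairs", cadence=1.3, amplitude=2.0, noise_sd=0.30,
                                     harmonics=(1.0, 0.70, 0.10), axis_weights=(0.8, 0.6, 0.25)),
    "descending_stairs": ActivitySpec("descending_stairs", cadence=1.7, amplitude=3.2, noise_sd=0.35,
                                      harmonics=(1.0, 0.25, 0.50), axis_weights=(0.95, 0.4, 0.35)),
    "sit_to_stand": ActivitySpec("sit_to_stand", amplitude=3.0, noise_sd=0.15, rise_exponent=0.55),
    "stand_to_sit": ActivitySpec("stand_to_sit", amplitude=2.6, noise_sd=0.15, rise_exponent=1.8),
    "jogging": ActivitySpec("jogging", cadence=2.7, amplitude=6.0, noise_sd=0.50,
                            harmonics=(1.0, 0.35, 0.12), axis_weights=(1.0, 0.55, 0.35)),
    "cycling": ActivitySpec("cycling", cadence=1.4, amplitude=1.1, noise_sd=0.12,
                            harmonics=(1.0, 0.06), axis_weights=(1.0, 0.35, 0.10)),
    "stationary": ActivitySpec("stationary", noise_sd=0.05),
}

#: Per-activity seconds mirroring the source training mix, scaled down 20x.
DEFAULT_DURATIONS: dict[str, int] = {
    "walking": 280,
    "ascending_stairs": 28,
    "descending_stairs": 21,
    "sit_to_stand": 14,
    "stand_to_sit": 14,
    "jogging": 217,
    "cycling": 155,
}


@dataclass
class DaySchedule:
    """An ordered list of (activity spec or name, duration in seconds) bouts."""

    entries: Sequence[tuple[ActivitySpec | str, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        resolved = []
        total = 0.0
        for spec, dur in self.entries:
            if dur <= 0:
                raise ValueError("bout durations must be positive")
            total += dur
            if isinstance(spec, str):
                spec = get_spec(spec)
            resolved.append((spec, float(dur)))
        if total > 24 * 3600:
            raise ValueError("schedule longer than 24 h")
        self.entries = resolved


def get_spec(activity: str) -> ActivitySpec:
    try:
        return replace(DEFAULT_SPECS[activity])
    except KeyError:
        raise ValueError(f"unknown activity {activity!r}; known: {sorted(DEFAULT_SPECS)}") from None


def random_orientation(rng: np.random.Generator, max_angle_deg: float = 15.0) -> np.ndarray:
    """Random axis sign flips composed with a small 3D rotation.

    Rectification removes sign flips exactly; the small rotation leaves a
    residual orientation effect the classifier must tolerate.
    """
    angles = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    signs = np.diag(rng.choice([-1.0, 1.0], size=3))
    return signs @ rz @ ry @ rx


def _transient_pulse(n: int, rise_exponent: float) -> np.ndarray:
    """A smooth one-sided pulse over n samples with tunable time asymmetry."""
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    return np.sin(np.pi * u ** rise_exponent) ** 2


def synth_activity(
    spec: ActivitySpec,
    duration: float,
    seed: int,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> Recording:
    """Generate one labeled bout of a single activity.

    Gravity sits on the first pre-orientation axis; locomotor classes add their
    harmonic stack, transitions one transient per second, and every axis gets
    i.i.d. Gaussian noise. Labels are per second; "stationary" bouts are
    labeled "sitting_or_standing" (the pipeline's output vocabulary).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if spec.activity not in DEFAULT_SPECS:
        raise ValueError(f"unknown activity {spec.activity!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6A6F6C6F]))
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    sig = np.zeros((3, n))
    sig[0] += GRAVITY

    if spec.activity in CYCLIC_ACTIVITIES and spec.cadence > 0:
        for axis in range(3):
            for h, weight in enumerate(spec.harmonics, start=1):
                if weight == 0:
                    continue
                amp = spec.amplitude * spec.axis_weights[axis] * weight
                # the vertical fundamental keeps phase 0 so it dominates the resultant
                phase = 0.0 if (axis == 0 and h == 1) else rng.uniform(0, 2 * np.pi)
                sig[axis] += amp * np.sin(2 * np.pi * h * spec.cadence * t + phase)
    elif spec.activity in TRANSITION_ACTIVITIES:
        per_second = int(sample_rate)
        pulse = _transient_pulse(per_second, spec.rise_exponent)
        for s in range(int(np.ceil(n / per_second))):
            lo, hi = s * per_second, min((s + 1) * per_second, n)
            jitter = rng.uniform(0.85, 1.15)
            sig[0, lo:hi] += spec.amplitude * jitter * pulse[: hi - lo]
            sig[1, lo:hi] += 0.4 * spec.amplitude * jitter * pulse[: hi - lo]

    if spec.noise_sd > 0:
        sig += rng.normal(0.0, spec.noise_sd, size=sig.shape)
    if spec.orientation is not None:
        sig = np.asarray(spec.orientation) @ sig

    label = SITTING_OR_STANDING if spec.activity == "stationary" else spec.activity
    labels = np.asarray([label] * int(n // sample_rate), dtype=object)
    return Recording(sig[0], sig[1], sig[2], sample_rate=sample_rate, labels=labels)


def synth_subject_set(
    n_subjects: int,
    durations: Mapping[str, float] | None = None,
    seed: int = 0,
    specs: Mapping[str, ActivitySpec] | None = None,
) -> dict[str, list[Recording]]:
    """Labeled recordings for several subjects, grouped for leave-one-subject-out.

    Each subject gets a reproducible cadence/amplitude offset (about 5% / 8%
    coefficient of variation) and a random phone orientation. Durations default
    to the scaled training mix in :data:`DEFAULT_DURATIONS`.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (leave-one-subject-out is undefined for 1)")
    durations = dict(durations or DEFAULT_DURATIONS)
    specs = specs or DEFAULT_SPECS
    root = np.random.SeedSequence([seed, 0x5E7])
    out: dict[str, list[Recording]] = {}
    for subj_idx, subj_seq in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(subj_seq)
        cad_mult = float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15))
        amp_mult = float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.25))
        orientation = random_orientation(rng)
        recs = []
        for activity, dur in durations.items():
            base = specs[activity]
            spec = replace(
                base,
                cadence=base.cadence * cad_mult,
                amplitude=base.amplitude * amp_mult,
                orientation=orientation,
            )
            recs.append(synth_activity(spec, dur, seed=int(rng.integers(2**31 - 1))))
        out[f"s{subj_idx}"] = recs
    return out


def synth_day(
    schedule: DaySchedule,
    t0: pd.Timestamp | None = None,
) -> tuple[Recording, np.ndarray, dict[str, float]]:
    """Concatenate scheduled bouts into one recording with exact ground truth.

    Returns the recording, the per-second truth labels, and per-activity truth
    counts: ``round(cadence x duration)`` cycles for cyclic bouts and one
    repetition per scheduled bout for sit/stand transitions.
    """
    if t0 is None:
        t0 = pd.Timestamp("2026-01-05 08:00:00")
    rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, 0xDA7]))
    parts: list[Recording] = []
    labels: list[np.ndarray] = []
    counts: dict[str, float] = {}
    for spec, dur in schedule.entries:
        rec = synth_activity(spec, dur, seed=int(rng.integers(2**31 - 1)))
        parts.append(rec)
        labels.append(rec.labels)
        if spec.activity in CYCLIC_ACTIVITIES:
            counts[spec.activity] = counts.get(spec.activity, 0) + round(spec.cadence * dur)
        elif spec.activity in TRANSITION_ACTIVITIES:
            counts[spec.activity] = counts.get(spec.activity, 0) + 1
    if not parts:
        empty = Recording(np.empty(0), np.empty(0), np.empty(0), t0=t0)
        return empty, np.empty(0, dtype=object), {}
    rec = Recording(
        np.concatenate([p.ax for p in parts]),
        np.concatenate([p.ay for p in parts]),
        np.concatenate([p.az for p in parts]),
        sample_rate=parts[0].sample_rate,
        t0=t0,
        labels=np.concatenate(labels) if labels else None,
    )
    return rec, rec.labels, counts


def recording_to_frame(rec: Recording, t0: pd.Timestamp | None = None) -> pd.DataFrame:
    """Serialize a recording to the chunk-CSV layout (timestamp,ax,ay,az[,label])."""
    t0 = t0 or rec.t0 or pd.Timestamp("2026-01-05 08:00:00")
    ts = t0 + pd.to_timedelta(np.arange(rec.n_samples) / rec.sample_rate, unit="s")
    df = pd.DataFrame({"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"), "ax": rec.ax, "ay": rec.ay, "az": rec.az})
    if rec.labels is not None:
        sec = (np.arange(rec.n_samples) // rec.sample_rate).astype(int)
        sec = np.clip(sec, 0, len(rec.labels) - 1)
        df["label"] = np.asarray(rec.labels, dtype=object)[sec]
    return df
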