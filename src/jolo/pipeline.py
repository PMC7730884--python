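"""End-to-end orchestration: raw chunk files to daily summaries.

The pipeline reads sensor chunks, rectifies and windows them, applies the
trained classifier, postprocesses labels (stationary rule, reject option),
counts cycles, scores functional status per calendar day and evaluates goals.
Every output carries the SHA-256 hash of the configuration that produced it,
and a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import jolo
from jolo.model import ActivityModel, load_model, predict_proba
from jolo.postprocess import CycleCounts, PostprocessConfig, count_cycles, estimate_cadence, postprocess_labels
from jolo.scoring import DEFAULT_POINT_TARGET, Goal, assign_profile, evaluate_goals, score_day
from jolo.signal_io import Recording, SegmentationConfig, read_accel_csv, windows_from_recording

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a scoring run needs besides the input chunks."""

    model_path: str
    out_dir: str
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    diagnosis: str = "KneeOA"
    point_target: float = DEFAULT_POINT_TARGET
    goals: tuple[Goal, ...] = ()
    seed: int = 0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # the analysis is the same wherever it is written
        payload["package_version"] = jolo.__version__
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _merge_chunks(recs: list[Recording], max_gap_intervals: float = 2.0) -> list[Recording]:
    """Join upload chunks whose timestamps are contiguous into single streams.

    Chunks are sorted by start time; a chunk starting within
    ``max_gap_intervals`` sample intervals of the previous chunk's end is
    concatenated (windows may then span the former boundary), otherwise a new
    stream starts.
    """
    recs = [r for r in recs if r.n_samples > 0]
    if not recs:
        raise ValueError("all chunks were empty")
    if any(r.t0 is None for r in recs):
        return recs
    recs = sorted(recs, key=lambda r: r.t0)
    merged: list[Recording] = []
    for rec in recs:
        if merged:
            prev = merged[-1]
            prev_end = prev.t0 + pd.Timedelta(seconds=prev.n_samples / prev.sample_rate)
            gap = (rec.t0 - prev_end).total_seconds()
            if 0 <= gap <= max_gap_intervals / rec.sample_rate and prev.sample_rate == rec.sample_rate:
                merged[-1] = Recording(
                    np.concatenate([prev.ax, rec.ax]),
                    np.concatenate([prev.ay, rec.ay]),
                    np.concatenate([prev.az, rec.az]),
                    sample_rate=prev.sample_rate,
                    t0=prev.t0,
                    splits=prev.splits + [s + prev.n_samples for s in rec.splits],
                )
                continue
        merged.append(rec)
    return merged


def run_pipeline(chunks: Sequence[str | Path], cfg: PipelineConfig) -> dict:
    """Process raw chunk files into per-day summaries under ``cfg.out_dir``.

    Writes ``predictions.csv`` (per-second class probabilities),
    ``labels.csv`` (final labels and cadence per second), ``counts.json``,
    ``summary.json`` (per-day seconds, cycles, functional status, goal
    progress) and ``manifest.json``. Returns the summary dict.
    """
    if not chunks:
        raise ValueError("no input chunks given")
    model_path = Path(cfg.model_path)
    if not model_path.exists():
        raise FileNotFoundError(
            f"model file {model_path} not found; train one with `jolo train --out {model_path}`"
        )
    model = load_model(model_path)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    streams = _merge_chunks([read_accel_csv(c) for c in sorted(str(c) for c in chunks)])
    first_t0 = min(s.t0 for s in streams if s.t0 is not None) if any(s.t0 is not None for s in streams) else None

    pred_frames = []
    label_rows = []
    day_windows: dict[str, list] = {}
    day_labels: dict[str, list] = {}
    for rec in streams:
        windows = windows_from_recording(rec, cfg.segmentation)
        if not windows:
            logger.warning("a stream shorter than one window was skipped")
            continue
        prob = predict_proba(model, windows)
        labels = postprocess_labels(prob, windows, cfg.postprocess)
        t0 = rec.t0 if rec.t0 is not None else pd.Timestamp("1970-01-01")
        times = t0 + pd.to_timedelta(prob.seconds, unit="s")
        pf = prob.to_frame()
        if first_t0 is not None:  # seconds global to the whole run, not per stream
            pf["second"] = ((times - first_t0).total_seconds()).astype(int)
        pf.insert(0, "timestamp", times.strftime("%Y-%m-%dT%H:%M:%S"))
        pred_frames.append(pf)
        for i, (ts, lab) in enumerate(zip(times, labels.to_numpy())):
            cad = estimate_cadence(windows[i], rec.sample_rate, cfg.postprocess) if lab in jolo.CYCLIC_ACTIVITIES else 0.0
            label_rows.append({"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"), "label": lab, "cadence_hz": round(cad, 4)})
            day = str(ts.date())
            day_windows.setdefault(day, []).append(windows[i])
            day_labels.setdefault(day, []).append(lab)

    if not label_rows:
        raise ValueError("no windows could be formed from the given chunks")

    profile, joints = assign_profile(cfg.diagnosis)
    days = {}
    total_counts = CycleCounts()
    for day in sorted(day_windows):
        labels = pd.Series(day_labels[day], dtype=object)
        counts = count_cycles(labels, day_windows[day], cfg.postprocess)
        total_counts = total_counts + counts
        status = {
            joint: score_day(counts, profile, joint, cfg.point_target) for joint in joints
        }
        expected = 86400 - 2  # the last two seconds of a full day have no window
        days[day] = {
            "seconds": counts.seconds,
            "cycles": {k: round(v, 2) for k, v in counts.cycles.items()},
            "partial_day": counts.total_seconds() < expected,
            "functional_status": {
                joint: {
                    "points_earned": round(st.points_earned, 2),
                    "point_target": st.point_target,
                    "fraction": round(st.fraction, 4),
                    "breakdown": {k: round(v, 2) for k, v in st.breakdown.items()},
                }
                for joint, st in status.items()
            },
        }

    goal_progress = []
    if cfg.goals:
        streams = {day: pd.Series(day_labels[day], dtype=object) for day in day_labels}
        for gp in evaluate_goals(streams, list(cfg.goals)):
            goal_progress.append(
                {
                    "activity": gp.goal.activity,
                    "duration_min": gp.goal.duration_min,
                    "frequency_per_week": gp.goal.frequency_per_week,
                    "qualifying_minutes_per_day": {d: round(m, 2) for d, m in gp.qualifying_minutes_per_day.items()},
                    "sessions": gp.sessions,
                    "achieved": gp.achieved,
                }
            )

    summary = {
        "config_hash": chash,
        "profile": profile.name,
        "joints": list(joints),
        "days": days,
        "goals": goal_progress,
    }
    _write_csv(pd.concat(pred_frames, ignore_index=True), out_dir / "predictions.csv", chash)
    _write_csv(pd.DataFrame(label_rows), out_dir / "labels.csv", chash)
    (out_dir / "counts.json").write_text(
        json.dumps(
            {"config_hash": chash, "cycles": {k: round(v, 2) for k, v in total_counts.cycles.items()},
             "seconds": total_counts.seconds},
            indent=2, sort_keys=True, default=_json_default,
        )
    )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    manifest = {
        "config_hash": chash,
        "package_version": jolo.__version__,
        "inputs": sorted(str(c) for c in chunks),
        "config": dataclasses.asdict(cfg),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return summary
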