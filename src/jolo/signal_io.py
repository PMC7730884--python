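"""Reading, orientation rectification and windowing of raw accelerometer streams.

The sensor stream is three synchronized series ``ax, ay, az`` in m/s^2, gravity
included, sampled at 50 Hz with the phone in an arbitrary orientation inside a
hip bag. Rectification (element-wise absolute value per axis) makes the stream
invariant to axis sign flips, so downstream stages never see orientation signs.
Classification operates on 3 s (150-sample) windows advanced by 1 s (50 samples),
one window per second of data.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 50.0


@dataclass
class Recording:
    """A uniformly sampled tri-axial acceleration series.

    Parameters
    ----------
    ax, ay, az : ndarray
        Acceleration per axis in m/s^2, gravity included. Equal lengths.
    sample_rate : float
        Samples per second; all shipped constants assume 50 Hz.
    t0 : pandas.Timestamp, optional
        Wall-clock time of the first sample.
    labels : ndarray of str, optional
        One activity label per whole second (``floor(n_samples / sample_rate)``
        entries), used for training data.
    splits : list of int
        Sample indices at which the stream was broken by an upload gap; windows
        never span a split. Index 0 is implicit and not listed.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    t0: pd.Timestamp | None = None
    labels: np.ndarray | None = None
    splits: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=np.float64)
        self.ay = np.asarray(self.ay, dtype=np.float64)
        self.az = np.asarray(self.az, dtype=np.float64)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis series must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.sample_rate != DEFAULT_SAMPLE_RATE:
            logger.warning(
                "sample_rate %.3g Hz differs from the 50 Hz the shipped model and "
                "constants assume",
                self.sample_rate,
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            expected = int(len(self.ax) // self.sample_rate)
            if len(self.labels) != expected:
                raise ValueError(
                    f"expected {expected} per-second labels for {len(self.ax)} samples, "
                    f"got {len(self.labels)}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def axes(self) -> np.ndarray:
        """Stack the three axis series into an (n_samples, 3) array."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass(frozen=True)
class SegmentationConfig:
    """Sliding-window parameters: 3 s windows advanced by 1 s at 50 Hz."""

    window_samples: int = 150
    step_samples: int = 50

    def __post_init__(self) -> None:
        if not (self.window_samples >= self.step_samples >= 1):
            raise ValueError("require window_samples >= step_samples >= 1")


@dataclass
class Window:
    """A rectified 150-sample segment; the unit of classification.

    ``rx, ry, rz`` are the absolute-valued axis segments; ``start_index`` is the
    sample offset into the parent recording, ``label`` the inherited activity
    label for training windows.
    """

    start_index: int
    rx: np.ndarray
    ry: np.ndarray
    rz: np.ndarray
    label: str | None = None

    def resultant(self) -> np.ndarray:
        """Per-sample resultant acceleration sqrt(ax^2+ay^2+az^2); sign-invariant."""
        return np.sqrt(self.rx**2 + self.ry**2 + self.rz**2)


def _parse_timestamps(col: pd.Series) -> pd.Series:
    """Timestamps are either epoch milliseconds or ISO-8601 strings."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return pd.to_datetime(numeric, unit="ms")
    return pd.to_datetime(col, format="ISO8601")


def _read_one_csv(text: str, name: str) -> pd.DataFrame:
    df = pd.read_csv(StringIO(text))
    missing = {"timestamp", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing required column(s) {sorted(missing)}")
    for axis in ("ax", "ay", "az"):
        values = pd.to_numeric(df[axis], errors="coerce")
        bad = values.isna() & df[axis].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{name}: non-numeric value {df[axis].iloc[row]!r} in column {axis}, row {row + 2}")
        if values.isna().any():
            row = int(np.flatnonzero(values.isna().to_numpy())[0])
            raise ValueError(f"{name}: empty cell in column {axis}, row {row + 2}")
        df[axis] = values
    return df


def read_accel_csv(
    path: str | Path,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    max_gap_intervals: float = 2.0,
) -> Recording:
    """Read a sensor chunk file (or a zip archive of chunk files) into a Recording.

    Expected header ``timestamp,ax,ay,az`` with an optional fifth ``label``
    column for training data. Timestamps must be monotone; gaps longer than
    ``max_gap_intervals`` sample intervals are logged and recorded as split
    markers so that no window spans them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".zip":
        frames = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.endswith(".csv"):
                    frames.append(_read_one_csv(zf.read(name).decode("utf-8"), name))
        if not frames:
            raise ValueError(f"{path}: archive contains no .csv members")
        df = pd.concat(frames, ignore_index=True)
    else:
        df = _read_one_csv(path.read_text(), path.name)

    if len(df) == 0:
        return Recording(np.empty(0), np.empty(0), np.empty(0), sample_rate=sample_rate)

    ts = _parse_timestamps(df["timestamp"])
    dt = ts.diff().dt.total_seconds().to_numpy()
    if np.any(dt[1:] < 0):
        raise ValueError(f"{path}: timestamps are not monotone non-decreasing")
    gap = 1.0 / sample_rate * max_gap_intervals
    splits = [int(i) for i in np.flatnonzero(dt > gap)]
    for i in splits:
        logger.warning("%s: %.3f s gap at sample %d; stream split, windows will not span it", path.name, dt[i], i)

    labels = None
    if "label" in df.columns:
        n_seconds = int(len(df) // sample_rate)
        per_second = []
        for s in range(n_seconds):
            block = df["label"].iloc[int(s * sample_rate) : int((s + 1) * sample_rate)]
            per_second.append(block.mode().iloc[0])
        labels = np.asarray(per_second, dtype=object)

    return Recording(
        df["ax"].to_numpy(),
        df["ay"].to_numpy(),
        df["az"].to_numpy(),
        sample_rate=sample_rate,
        t0=ts.iloc[0],
        labels=labels,
        splits=splits,
    )


def rectify(rec: Recording) -> Recording:
    """Absolute value per axis: removes phone orientation sign, keeps magnitude."""
    return replace(rec, ax=np.abs(rec.ax), ay=np.abs(rec.ay), az=np.abs(rec.az))


def n_windows(n_samples: int, cfg: SegmentationConfig = SegmentationConfig()) -> int:
    """Window count for a contiguous block of ``n_samples`` samples."""
    if n_samples < cfg.window_samples:
        return 0
    return (n_samples - cfg.window_samples) // cfg.step_samples + 1


def _window_label(rec: Recording, start: int, length: int) -> str | None:
    """Label of a window spanning samples [start, start+length).

    The window inherits the majority label among the whole seconds it overlaps;
    an exact tie goes to the earliest overlapped second's label.
    """
    if rec.labels is None or len(rec.labels) == 0:
        return None
    sr = rec.sample_rate
    first = int(start // sr)
    last = int((start + length - 1) // sr)
    seconds = [s for s in range(first, last + 1) if s < len(rec.labels)]
    if not seconds:
        return None
    votes: dict[str, int] = {}
    for s in seconds:
        votes[rec.labels[s]] = votes.get(rec.labels[s], 0) + 1
    best = max(votes.values())
    winners = {lab for lab, v in votes.items() if v == best}
    for s in seconds:  # earliest-second tie-break
        if rec.labels[s] in winners:
            return rec.labels[s]
    raise AssertionError("unreachable")


def segment(rec: Recording, cfg: SegmentationConfig = SegmentationConfig()) -> list[Window]:
    """Slice a (rectified) recording into sliding windows.

    Each contiguous block between split markers contributes
    ``floor((block_samples - window) / step) + 1`` windows; blocks shorter than
    one window contribute none, and edge remainders are dropped rather than
    padded. Labeled recordings propagate per-second labels to windows.
    """
    bounds = [0] + sorted(rec.splits) + [rec.n_samples]
    out: list[Window] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        for k in range(n_windows(b1 - b0, cfg)):
            start = b0 + k * cfg.step_samples
            stop = start + cfg.window_samples
            out.append(
                Window(
                    start_index=start,
                    rx=rec.ax[start:stop],
                    ry=rec.ay[start:stop],
                    rz=rec.az[start:stop],
                    label=_window_label(rec, start, cfg.window_samples),
                )
            )
    return out


def windows_from_recording(rec: Recording, cfg: SegmentationConfig = SegmentationConfig()) -> list[Window]:
    """Rectify then segment: the canonical ingestion path for raw recordings."""
    return segment(rectify(rec), cfg)
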