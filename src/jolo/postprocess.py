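"""Postprocessing of raw classifier output and cycle counting.

Two rules clean the free-living label stream:

1. Stationary rule. Sitting and standing are not classifier classes: a phone at
   rest is the one regime the classifier never saw, and it is trivially
   detectable. A second whose window has var(rx) below a threshold (default
   0.1 (m/s^2)^2) is labeled ``sitting_or_standing`` and bypasses the model;
   the learned model is applied otherwise.
2. Reject option. Where the model does run, the predicted label is kept only
   if the top class probability reaches a threshold delta (default 0.5);
   otherwise the second becomes ``unknown``. The delta sweep reports, per
   candidate threshold, the accuracy over retained seconds and the fraction
   of seconds retained, to support choosing delta.

Cadence is estimated per window from the discrete Fourier transform of the
resultant acceleration sqrt(ax^2+ay^2+az^2): the window mean is removed, the
150 samples are zero-padded to 512 (refining the native 1/3 Hz resolution to
~0.1 Hz), and the magnitude peak is taken over the physiological band
0.3-4.0 Hz. Cycle totals are the sum of per-second cadences over the seconds
carrying each cyclic label; sit/stand transitions are counted as maximal runs
of consecutive transition seconds (a single ~1 s transition spans up to three
overlapping windows, so raw window counts overcount; the raw count remains
available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from jolo.labels import (
    CYCLIC_ACTIVITIES,
    LABEL_VOCABULARY,
    SITTING_OR_STANDING,
    TRANSITION_ACTIVITIES,
    UNKNOWN,
)
from jolo.model import ProbSeries
from jolo.signal_io import DEFAULT_SAMPLE_RATE, Window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostprocessConfig:
    """Thresholds and cadence-estimation parameters.

    delta: minimum top-class probability to keep a prediction.
    stationary_var_threshold: var(rx) below which a window is at rest, (m/s^2)^2.
    cadence_band: search band for the spectral peak, Hz.
    pad_to: zero-padded DFT length (512 -> ~0.098 Hz bins at 50 Hz).
    amplitude_floor: minimum spectral amplitude (m/s^2) to report a nonzero
    cadence; below it the window has no periodic component worth counting.
    transitions_as_window_count: count each transition-labeled second as one
    repetition instead of merging consecutive seconds into runs.
    """

    delta: float = 0.5
    stationary_var_threshold: float = 0.1
    stationary_axis: str = "rx"
    cadence_band: tuple[float, float] = (0.3, 4.0)
    pad_to: int = 512
    amplitude_floor: float = 0.1
    transitions_as_window_count: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if self.stationary_var_threshold <= 0:
            raise ValueError("stationary_var_threshold must be positive")


def _check_vocabulary(labels: pd.Series) -> None:
    bad = set(labels.unique()) - set(LABEL_VOCABULARY)
    if bad:
        raise ValueError(f"labels outside the closed vocabulary: {sorted(bad)}")


def apply_unknown_threshold(prob: ProbSeries, delta: float = 0.5) -> pd.Series:
    """Keep the argmax label iff its probability reaches delta, else ``unknown``.

    Returns a per-second label series indexed by second offset.
    """
    labels = np.where(prob.p_max >= delta, prob.labels, UNKNOWN)
    return pd.Series(labels, index=prob.seconds, name="label", dtype=object)


def apply_stationary_rule(
    windows: list[Window],
    labels: pd.Series,
    cfg: PostprocessConfig = PostprocessConfig(),
) -> pd.Series:
    """Override labels with ``sitting_or_standing`` where the phone is at rest.

    A second is at rest when the variance of its window's rectified first axis
    (``cfg.stationary_axis``) is below ``cfg.stationary_var_threshold``. The
    rule bypasses the classifier entirely, so it overrides whatever label the
    model produced (including ``unknown``).
    """
    if len(windows) != len(labels):
        raise ValueError(f"{len(windows)} windows but {len(labels)} label seconds")
    variances = np.asarray([np.var(getattr(w, cfg.stationary_axis)) for w in windows])
    out = labels.copy()
    out.iloc[np.flatnonzero(variances < cfg.stationary_var_threshold)] = SITTING_OR_STANDING
    return out


def postprocess_labels(
    prob: ProbSeries,
    windows: list[Window],
    cfg: PostprocessConfig = PostprocessConfig(),
) -> pd.Series:
    """Both rules in their documented order: stationary detection, then reject option."""
    labels = apply_unknown_threshold(prob, cfg.delta)
    return apply_stationary_rule(windows, labels, cfg)


def sweep_delta(
    prob: ProbSeries,
    truth: np.ndarray | pd.Series,
    deltas: np.ndarray | list[float],
) -> pd.DataFrame:
    """Accuracy over retained seconds and retained fraction for each threshold.

    A second is retained when its top probability reaches delta; accuracy is
    computed against ``truth`` over retained seconds only. When nothing is
    retained the accuracy is NaN (logged).
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta grid")
    truth = np.asarray(truth, dtype=object)
    if len(truth) != len(prob):
        raise ValueError("truth and probability series must align")
    pred = prob.labels
    p_max = prob.p_max
    rows = []
    for d in deltas:
        retained = p_max >= d
        frac = float(retained.mean()) if len(retained) else 0.0
        if retained.any():
            acc = float((pred[retained] == truth[retained]).mean())
        else:
            acc = float("nan")
            logger.warning("delta %.3f retains no seconds; accuracy undefined", d)
        rows.append({"delta": float(d), "accuracy": acc, "retained_fraction": frac})
    return pd.DataFrame(rows)


def estimate_cadence(
    window: Window,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    cfg: PostprocessConfig = PostprocessConfig(),
) -> float:
    """Dominant frequency (Hz) of the window's resultant acceleration.

    The resultant is mean-subtracted (the ~9.81 m/s^2 gravity offset would
    otherwise leak into every zero-padded bin), zero-padded to ``cfg.pad_to``
    samples, and the DFT magnitude peak is located within ``cfg.cadence_band``.
    Returns 0.0 when the peak amplitude is below ``cfg.amplitude_floor`` —
    a stationary or aperiodic window has no cadence.
    """
    r = window.resultant()
    n = len(r)
    if n == 0:
        return 0.0
    pad = max(cfg.pad_to, n)
    mag = 2.0 * np.abs(np.fft.rfft(r - r.mean(), n=pad)) / n
    freqs = np.fft.rfftfreq(pad, d=1.0 / sample_rate)
    band = (freqs >= cfg.cadence_band[0]) & (freqs <= cfg.cadence_band[1])
    if not band.any():
        return 0.0
    band_idx = np.flatnonzero(band)
    k = int(band_idx[np.argmax(mag[band])])
    if mag[k] < cfg.amplitude_floor:
        return 0.0
    # parabolic interpolation of the peak removes the bin-quantization bias
    df = freqs[1] - freqs[0]
    if 0 < k < len(mag) - 1:
        denom = mag[k - 1] - 2 * mag[k] + mag[k + 1]
        if denom < 0:
            shift = 0.5 * (mag[k - 1] - mag[k + 1]) / denom
            return float(freqs[k] + np.clip(shift, -0.5, 0.5) * df)
    return float(freqs[k])


@dataclass
class CycleCounts:
    """Per-activity cycle/repetition totals and per-label second tallies."""

    cycles: dict[str, float] = field(default_factory=dict)
    seconds: dict[str, int] = field(default_factory=dict)

    def total_seconds(self) -> int:
        return sum(self.seconds.values())

    def __add__(self, other: "CycleCounts") -> "CycleCounts":
        cycles = dict(self.cycles)
        for k, v in other.cycles.items():
            cycles[k] = cycles.get(k, 0.0) + v
        seconds = dict(self.seconds)
        for k, v in other.seconds.items():
            seconds[k] = seconds.get(k, 0) + v
        return CycleCounts(cycles, seconds)


def _run_lengths(mask: np.ndarray) -> int:
    """Number of maximal runs of True."""
    if mask.size == 0:
        return 0
    starts = mask & ~np.concatenate([[False], mask[:-1]])
    return int(starts.sum())


def count_cycles(
    labels: pd.Series,
    windows: list[Window],
    cfg: PostprocessConfig = PostprocessConfig(),
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> CycleCounts:
    """Aggregate cycles per activity from the final label stream.

    Every second labeled with a cyclic activity contributes that window's
    estimated cadence x 1 s of cycles (strides, or pedal rotations for
    cycling). Transition repetitions are maximal runs of consecutive
    transition-labeled seconds (or raw second counts when
    ``cfg.transitions_as_window_count``). Seconds are tallied for every label
    including ``unknown`` and ``sitting_or_standing``.
    """
    if len(windows) != len(labels):
        raise ValueError(f"{len(windows)} windows but {len(labels)} label seconds")
    _check_vocabulary(labels)
    lab = labels.to_numpy(dtype=object)
    counts = CycleCounts()
    for name in LABEL_VOCABULARY:
        n_sec = int((lab == name).sum())
        if n_sec:
            counts.seconds[name] = n_sec
    for activity in CYCLIC_ACTIVITIES:
        mask = lab == activity
        if mask.any():
            total = sum(estimate_cadence(w, sample_rate, cfg) for w, m in zip(windows, mask) if m)
            counts.cycles[activity] = float(total)
    for activity in TRANSITION_ACTIVITIES:
        mask = lab == activity
        if mask.any():
            if cfg.transitions_as_window_count:
                counts.cycles[activity] = float(mask.sum())
            else:
                counts.cycles[activity] = float(_run_lengths(mask))
    return counts
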