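"""Window-level feature extraction.

Each 150-sample rectified axis signal is summarized by a fixed catalog of
scalar features covering three families: distributional (moments, quantiles,
energy), temporal (changes, crossings, autocorrelation, time-reversal
asymmetry, linear trend) and spectral (zero-padded-free DFT magnitudes of the
demeaned signal, band powers, spectral centroid and entropy). The catalog is
applied identically to the three rectified axes, giving a feature matrix with
``3 x catalog`` named columns, one row per window.

The catalog is fixed and versioned with the package: the selection step (see
:mod:`jolo.model`) decides which columns carry class information, so the
catalog errs on the side of redundancy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from jolo.signal_io import DEFAULT_SAMPLE_RATE, Window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction and selection parameters.

    fft_bins DFT magnitude bins are kept (bin k of a 150-sample window at
    50 Hz sits at k/3 Hz, so 25 bins span 1/3 to 8.33 Hz). fdr_level is the
    Benjamini-Yekutieli false-discovery level of the relevance filter.
    """

    fft_bins: int = 25
    acf_lags: tuple[int, ...] = (1, 2, 5, 10, 25, 50)
    trev_lags: tuple[int, ...] = (5, 10)
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.fft_bins < 1:
            raise ValueError("fft_bins must be >= 1")


def _autocorrelation(X: np.ndarray, lag: int) -> np.ndarray:
    n = X.shape[1]
    if lag >= n:
        return np.zeros(X.shape[0])
    mu = X.mean(axis=1, keepdims=True)
    var = X.var(axis=1)
    num = ((X[:, :-lag] - mu) * (X[:, lag:] - mu)).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, num / var, 0.0)


def _time_reversal_asymmetry(X: np.ndarray, lag: int) -> np.ndarray:
    """E[x_{t+2l}^2 x_{t+l} - x_{t+l} x_t^2]; zero for time-symmetric signals."""
    n = X.shape[1]
    if 2 * lag >= n:
        return np.zeros(X.shape[0])
    a, b, c = X[:, 2 * lag :], X[:, lag : n - lag], X[:, : n - 2 * lag]
    return (a**2 * b - b * c**2).mean(axis=1)


def _per_signal_features(X: np.ndarray, sample_rate: float, cfg: FeatureConfig) -> dict[str, np.ndarray]:
    """Catalog applied to a batch of signals, shape (n_windows, window_samples)."""
    n, L = X.shape
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    out: dict[str, np.ndarray] = {}

    # distributional
    out["mean"] = mu
    out["std"] = sd
    out["var"] = X.var(axis=1)
    out["min"] = X.min(axis=1)
    out["max"] = X.max(axis=1)
    out["median"] = np.median(X, axis=1)
    out["ptp"] = out["max"] - out["min"]
    for q in (5, 10, 25, 75, 90, 95):
        out[f"q{q:02d}"] = np.percentile(X, q, axis=1)
    out["iqr"] = out["q75"] - out["q25"]
    with warnings.catch_warnings():
        # constant windows legitimately yield nan moments; replaced by 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        out["skewness"] = stats.skew(X, axis=1)
        out["kurtosis"] = stats.kurtosis(X, axis=1)
    out["rms"] = np.sqrt((X**2).mean(axis=1))
    out["abs_energy"] = (X**2).sum(axis=1)

    # temporal
    diff = np.diff(X, axis=1)
    out["mean_abs_change"] = np.abs(diff).mean(axis=1)
    out["max_abs_change"] = np.abs(diff).max(axis=1)
    out["mean_change"] = diff.mean(axis=1)
    out["mean_second_derivative"] = (X[:, 2:] - 2 * X[:, 1:-1] + X[:, :-2]).mean(axis=1)
    above = X > mu[:, None]
    out["count_above_mean"] = above.sum(axis=1).astype(float)
    out["mean_crossings"] = (above[:, 1:] != above[:, :-1]).sum(axis=1).astype(float)
    out["first_location_of_max"] = X.argmax(axis=1) / L
    out["first_location_of_min"] = X.argmin(axis=1) / L
    for lag in cfg.acf_lags:
        out[f"acf_lag{lag}"] = _autocorrelation(X, lag)
    for lag in cfg.trev_lags:
        out[f"trev_lag{lag}"] = _time_reversal_asymmetry(X, lag)
    t = np.arange(L) - (L - 1) / 2
    out["linear_trend_slope"] = (X * t).sum(axis=1) / (t**2).sum()

    # spectral, on the demeaned signal so gravity does not swamp the low bins
    spec = np.fft.rfft(X - mu[:, None], axis=1)
    mag = 2.0 * np.abs(spec) / L
    freqs = np.fft.rfftfreq(L, d=1.0 / sample_rate)
    kmax = min(cfg.fft_bins, mag.shape[1] - 1)
    for k in range(1, kmax + 1):
        out[f"fft_mag_{freqs[k]:.2f}hz"] = mag[:, k]
    power = mag[:, 1:] ** 2
    total = power.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total[:, None] > 0, power / total[:, None], 0.0)
        out["spectral_centroid_hz"] = (p * freqs[1:]).sum(axis=1)
        plog = np.where(p > 0, p * np.log(p), 0.0)
        out["spectral_entropy"] = -plog.sum(axis=1)
    out["peak_freq_hz"] = freqs[1:][power.argmax(axis=1)]
    out["peak_mag"] = mag[:, 1:].max(axis=1)
    for name, lo, hi in (("low", 0.3, 1.0), ("mid", 1.0, 2.5), ("high", 2.5, 8.0)):
        band = (freqs[1:] >= lo) & (freqs[1:] < hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"bandpower_{name}_frac"] = np.where(total > 0, power[:, band].sum(axis=1) / total, 0.0)
    return out


def extract_features(
    windows: list[Window],
    cfg: FeatureConfig = FeatureConfig(),
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> pd.DataFrame:
    """One feature row per window; columns ``{axis}__{feature}`` over rx, ry, rz.

    Degenerate signals (constant, all-zero) can yield NaN/inf in ratio-based
    features; these are replaced by 0 with a log warning. Deterministic.
    """
    if not windows:
        raise ValueError("extract_features requires a non-empty window list")
    lengths = {len(w.rx) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    cols: dict[str, np.ndarray] = {}
    for axis in ("rx", "ry", "rz"):
        X = np.stack([getattr(w, axis) for w in windows]).astype(np.float64)
        for name, values in _per_signal_features(X, sample_rate, cfg).items():
            cols[f"{axis}__{name}"] = values
    out = pd.DataFrame(cols)
    bad = ~np.isfinite(out.to_numpy())
    if bad.any():
        logger.warning("replaced %d non-finite feature values with 0", int(bad.sum()))
        out = out.where(np.isfinite(out), 0.0)
    return out
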