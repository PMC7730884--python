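"""Activity classification: feature selection, boosted trees, LOSO evaluation.

The classifier is a gradient-boosted decision-tree ensemble over the window
features of :mod:`jolo.features`, restricted to the features that pass a
rank-based relevance filter: every feature is tested against every one-vs-rest
class indicator with a two-sided Mann-Whitney U test and the pooled p-values
are controlled with the Benjamini-Yekutieli procedure (valid under arbitrary
dependence among features). A feature is kept if any of its class tests
survives. Generalization across people is measured with leave-one-subject-out
cross-validation: the relevance filter and the ensemble are re-fitted inside
every fold, so no information from the held-out subject leaks into training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from jolo.features import FeatureConfig, extract_features
from jolo.labels import ACTIVITIES
from jolo.signal_io import Recording, SegmentationConfig, Window, windows_from_recording

logger = logging.getLogger(__name__)

DEFAULT_HYPERPARAMS = {"n_estimators": 500, "max_depth": 6, "learning_rate": 0.1, "num_leaves": 63}


@dataclass
class ProbSeries:
    """Per-second class-probability vectors.

    ``probabilities`` has one row per second (= per window) and one column per
    activity class; every row is a probability simplex. ``seconds`` gives the
    second offset of each row within the recording.
    """

    probabilities: pd.DataFrame
    seconds: np.ndarray

    def __post_init__(self) -> None:
        self.seconds = np.asarray(self.seconds, dtype=np.int64)
        if len(self.probabilities) != len(self.seconds):
            raise ValueError("seconds and probability rows must align")
        p = self.probabilities.to_numpy()
        if len(p) and ((p < -1e-12).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-9):
            raise ValueError("probability rows must be non-negative and sum to 1")

    def __len__(self) -> int:
        return len(self.seconds)

    @property
    def labels(self) -> np.ndarray:
        """Argmax class per row."""
        if len(self) == 0:
            return np.empty(0, dtype=object)
        return self.probabilities.columns.to_numpy(dtype=object)[
            self.probabilities.to_numpy().argmax(axis=1)
        ]

    @property
    def p_max(self) -> np.ndarray:
        if len(self) == 0:
            return np.empty(0)
        return self.probabilities.to_numpy().max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Serialized layout: second, label, p_max, then one p_<class> column per class."""
        df = pd.DataFrame({"second": self.seconds, "label": self.labels, "p_max": self.p_max})
        for c in self.probabilities.columns:
            df[f"p_{c}"] = self.probabilities[c].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbSeries":
        classes = [c[2:] for c in df.columns if c.startswith("p_") and c != "p_max"]
        probs = df[[f"p_{c}" for c in classes]].to_numpy()
        return cls(pd.DataFrame(probs, columns=classes), df["second"].to_numpy())


def select_features(X: pd.DataFrame, y: Sequence[str], fdr_level: float = 0.05) -> list[str]:
    """Rank-based relevance filter with Benjamini-Yekutieli FDR control.

    Each feature is compared between one class and the rest with a two-sided
    Mann-Whitney U test, for every class; all (feature, class) p-values are
    pooled and BY-corrected at ``fdr_level``. Features with at least one
    rejected test are returned in their original column order.
    """
    y = np.asarray(y, dtype=object)
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("feature selection requires at least 2 classes")
    if len(X) < 10:
        raise ValueError("feature selection requires at least 10 rows")
    values = X.to_numpy()
    pvals = np.ones((len(classes), values.shape[1]))
    for i, c in enumerate(classes):
        mask = y == c
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(values[mask], values[~mask], alternative="two-sided", axis=0)
        pvals[i] = np.nan_to_num(res.pvalue, nan=1.0)
    reject, *_ = multipletests(pvals.ravel(), alpha=fdr_level, method="fdr_by")
    keep = reject.reshape(pvals.shape).any(axis=0)
    selected = [c for c, k in zip(X.columns, keep) if k]
    if not selected:
        raise ValueError("no relevant features at the requested FDR level")
    return selected


@dataclass
class ActivityModel:
    """A fitted boosted-tree activity classifier plus everything needed to apply it."""

    booster: lgb.LGBMClassifier
    classes: tuple[str, ...]
    selected_features: list[str]
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    seed: int = 0


def train(
    X: pd.DataFrame,
    y: Sequence[str],
    seed: int = 0,
    selected_features: Sequence[str] | None = None,
    feature_config: FeatureConfig = FeatureConfig(),
    hyperparams: Mapping | None = None,
) -> ActivityModel:
    """Fit the boosted-tree ensemble on (already selected) window features.

    ``selected_features`` restricts the columns used; pass the output of
    :func:`select_features`. Training is deterministic for a fixed seed.
    """
    y = np.asarray(y, dtype=object)
    present = set(pd.unique(y))
    unknown = present - set(ACTIVITIES)
    if unknown:
        raise ValueError(f"labels outside the activity vocabulary: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes")
    if present != set(ACTIVITIES):
        logger.warning("training on %d of 7 activity classes: %s", len(present), sorted(present))
    cols = list(selected_features) if selected_features is not None else list(X.columns)
    params = dict(DEFAULT_HYPERPARAMS)
    params.update(hyperparams or {})
    clf = lgb.LGBMClassifier(
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
        **params,
    )
    clf.fit(X[cols], y)
    return ActivityModel(
        booster=clf,
        classes=tuple(clf.classes_),
        selected_features=cols,
        feature_config=feature_config,
        hyperparams=params,
        seed=seed,
    )


def fit_from_recordings(
    recordings: Sequence[Recording],
    seed: int = 0,
    feature_config: FeatureConfig = FeatureConfig(),
    segmentation: SegmentationConfig = SegmentationConfig(),
    hyperparams: Mapping | None = None,
) -> ActivityModel:
    """Full training path from labeled recordings: windowing, extraction, selection, fit."""
    X, y = _subject_features(recordings, feature_config, segmentation)
    selected = select_features(X, y, feature_config.fdr_level)
    return train(X, y, seed=seed, selected_features=selected,
                 feature_config=feature_config, hyperparams=hyperparams)


def predict_proba(model: ActivityModel, windows: list[Window]) -> ProbSeries:
    """Per-window class probabilities, one row per second of the stream.

    Rows are indexed by the window start second (start_index / 50 at the
    default rate); classes missing from the training data get probability 0.
    """
    if not windows:
        return ProbSeries(pd.DataFrame(columns=list(ACTIVITIES)), np.empty(0, dtype=int))
    X = extract_features(windows, model.feature_config)
    missing = [c for c in model.selected_features if c not in X.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns {missing[:5]}...")
    raw = model.booster.predict_proba(X[model.selected_features])
    probs = pd.DataFrame(0.0, index=range(len(windows)), columns=list(ACTIVITIES))
    probs.loc[:, list(model.classes)] = raw
    step = model.segmentation.step_samples
    seconds = np.asarray([w.start_index // step for w in windows])
    return ProbSeries(probs, seconds)


@dataclass
class LosoResult:
    """Pooled leave-one-subject-out evaluation output."""

    accuracy: float
    confusion: pd.DataFrame
    fold_accuracy: dict[str, float]
    predictions: dict[str, tuple[np.ndarray, np.ndarray]]
    """Per held-out subject: (truth labels, predicted labels) per window."""


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    """Row-normalized confusion matrix: rows = truth classes present, columns = activities."""
    ct = pd.crosstab(pd.Series(y_true, name="truth"), pd.Series(y_pred, name="prediction"))
    ct = ct.reindex(columns=[c for c in ACTIVITIES], fill_value=0)
    extra = [c for c in ct.columns if c not in ACTIVITIES]
    ct = ct[[*ACTIVITIES, *extra]]
    ct = ct.reindex(index=[c for c in ACTIVITIES if c in ct.index])
    return ct.div(ct.sum(axis=1), axis=0)


def _subject_features(
    recordings: Sequence[Recording],
    feature_config: FeatureConfig,
    segmentation: SegmentationConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    windows: list[Window] = []
    for rec in recordings:
        windows.extend(windows_from_recording(rec, segmentation))
    windows = [w for w in windows if w.label in ACTIVITIES]
    if not windows:
        raise ValueError("subject contributed no labeled windows")
    X = extract_features(windows, feature_config)
    y = np.asarray([w.label for w in windows], dtype=object)
    return X, y


def loso_evaluate(
    dataset: Mapping[str, Sequence[Recording]],
    feature_config: FeatureConfig = FeatureConfig(),
    segmentation: SegmentationConfig = SegmentationConfig(),
    seed: int = 0,
    hyperparams: Mapping | None = None,
    holdout_subjects: Sequence[str] | None = None,
) -> LosoResult:
    """Leave-one-subject-out cross-validation of the full train/predict path.

    For every held-out subject the relevance filter and the classifier are
    re-fitted on the remaining subjects' windows and applied to the held-out
    windows. Returns pooled per-window accuracy and a row-normalized confusion
    matrix. ``holdout_subjects`` restricts evaluation to selected folds.
    """
    subjects = list(dataset)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    folds = list(holdout_subjects) if holdout_subjects is not None else subjects
    cached = {s: _subject_features(dataset[s], feature_config, segmentation) for s in subjects}
    predictions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fold_accuracy: dict[str, float] = {}
    for held_out in folds:
        X_tr = pd.concat([cached[s][0] for s in subjects if s != held_out], ignore_index=True)
        y_tr = np.concatenate([cached[s][1] for s in subjects if s != held_out])
        selected = select_features(X_tr, y_tr, feature_config.fdr_level)
        model = train(X_tr, y_tr, seed=seed, selected_features=selected,
                      feature_config=feature_config, hyperparams=hyperparams)
        X_te, y_te = cached[held_out]
        raw = model.booster.predict_proba(X_te[model.selected_features])
        y_pred = np.asarray(model.classes, dtype=object)[raw.argmax(axis=1)]
        predictions[held_out] = (y_te, y_pred)
        fold_accuracy[held_out] = float((y_te == y_pred).mean())
        logger.info("fold %s: accuracy %.4f over %d windows", held_out, fold_accuracy[held_out], len(y_te))
    y_true = np.concatenate([predictions[s][0] for s in folds])
    y_pred = np.concatenate([predictions[s][1] for s in folds])
    return LosoResult(
        accuracy=float((y_true == y_pred).mean()),
        confusion=confusion_matrix(y_true, y_pred),
        fold_accuracy=fold_accuracy,
        predictions=predictions,
    )


def save_model(model: ActivityModel, path: str | Path) -> None:
    """Persist the model as a single JSON file (booster serialized as text)."""
    payload = {
        "format": "jolo-activity-model-v1",
        "classes": list(model.classes),
        "selected_features": model.selected_features,
        "feature_config": {
            "fft_bins": model.feature_config.fft_bins,
            "acf_lags": list(model.feature_config.acf_lags),
            "trev_lags": list(model.feature_config.trev_lags),
            "fdr_level": model.feature_config.fdr_level,
        },
        "segmentation": {
            "window_samples": model.segmentation.window_samples,
            "step_samples": model.segmentation.step_samples,
        },
        "hyperparams": model.hyperparams,
        "seed": model.seed,
        "booster": model.booster.booster_.model_to_string(),
    }
    Path(path).write_text(json.dumps(payload))


class _BoosterAdapter:
    """Minimal predict_proba facade over a raw LightGBM Booster."""

    def __init__(self, booster: lgb.Booster):
        self._booster = booster
        self.booster_ = booster

    def predict_proba(self, X) -> np.ndarray:
        p = np.asarray(self._booster.predict(X))
        if p.ndim == 1:  # binary boosters return P(class 1) only
            p = np.column_stack([1.0 - p, p])
        return p


def load_model(path: str | Path) -> ActivityModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "jolo-activity-model-v1":
        raise ValueError(f"{path}: not a recognized model file")
    fc = payload["feature_config"]
    seg = payload["segmentation"]
    return ActivityModel(
        booster=_BoosterAdapter(lgb.Booster(model_str=payload["booster"])),
        classes=tuple(payload["classes"]),
        selected_features=payload["selected_features"],
        feature_config=FeatureConfig(
            fft_bins=fc["fft_bins"],
            acf_lags=tuple(fc["acf_lags"]),
            trev_lags=tuple(fc["trev_lags"]),
            fdr_level=fc["fdr_level"],
        ),
        segmentation=SegmentationConfig(seg["window_samples"], seg["step_samples"]),
        hyperparams=payload["hyperparams"],
        seed=payload["seed"],
    )
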