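import numpy as np
import pytest

from jolo.labels import ACTIVITIES
from jolo.model import fit_from_recordings, loso_evaluate
from jolo.synthetic import synth_subject_set


@pytest.fixture(scope="session")
def loso_result():
    """Default-condition LOSO run: 5 subjects, scaled training mix, fixed seed."""
    dataset = synth_subject_set(5, seed=42)
    return loso_evaluate(dataset, seed=0)


@pytest.fixture(scope="session")
def permuted_fold_accuracy():
    """Accuracy of one LOSO fold after permuting the held-out subject's labels.

    Balanced durations make the permuted truth multiset uniform over the seven
    classes, so the expected retained accuracy is exactly 1/7 whatever the
    classifier predicts.
    """
    durations = {a: 30 for a in ACTIVITIES}
    dataset = synth_subject_set(5, durations=durations, seed=7)
    rng = np.random.default_rng(123)
    pooled = np.concatenate([r.labels for r in dataset["s0"]])
    pooled = rng.permutation(pooled)
    offset = 0
    for rec in dataset["s0"]:
        rec.labels = pooled[offset : offset + len(rec.labels)]
        offset += len(rec.labels)
    res = loso_evaluate(dataset, seed=0, holdout_subjects=["s0"])
    return res.fold_accuracy["s0"]


@pytest.fixture(scope="session")
def small_model():
    """A quickly trained classifier for pipeline and prediction tests."""
    durations = {
        "walking": 60, "ascending_stairs": 20, "descending_stairs": 20,
        "sit_to_stand": 8, "stand_to_sit": 8, "jogging": 40, "cycling": 30,
    }
    dataset = synth_subject_set(2, durations=durations, seed=5)
    recordings = [r for recs in dataset.values() for r in recs]
    return fit_from_recordings(recordings, seed=0, hyperparams={"n_estimators": 150})
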