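"""Reject option, stationary rule, cadence estimation and cycle counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jolo.labels import ACTIVITIES, SITTING_OR_STANDING, UNKNOWN
from jolo.model import ProbSeries
from jolo.postprocess import (
    CycleCounts,
    PostprocessConfig,
    apply_stationary_rule,
    apply_unknown_threshold,
    count_cycles,
    estimate_cadence,
    sweep_delta,
)
from jolo.signal_io import Window, windows_from_recording
from jolo.synthetic import get_spec, synth_activity


def prob_series(p_max_values, top_class="descending_stairs"):
    """Build a ProbSeries whose rows have the given top probability on one class."""
    rows = []
    for p in p_max_values:
        row = {c: (1 - p) / 6 for c in ACTIVITIES}
        row[top_class] = p
        rows.append(row)
    return ProbSeries(pd.DataFrame(rows)[list(ACTIVITIES)], np.arange(len(rows)))


def sine_window(freq, amplitude=1.0, offset=9.81, n=150, noise_sd=0.0, seed=0):
    t = np.arange(n) / 50.0
    rng = np.random.default_rng(seed)
    x = offset + amplitude * np.sin(2 * np.pi * freq * t) + rng.normal(0, noise_sd, n)
    flat = np.zeros(n)
    return Window(0, np.abs(x), flat, flat)


class TestUnknownThreshold:
    def test_low_confidence_descending_stairs_becomes_unknown(self):
        # top class 0.45 < delta 0.5 -> prediction withheld
        labels = apply_unknown_threshold(prob_series([0.45, 0.9]), delta=0.5)
        assert list(labels) == [UNKNOWN, "descending_stairs"]

    def test_delta_zero_is_argmax(self):
        ps = prob_series([0.2, 0.5, 0.99])
        assert list(apply_unknown_threshold(ps, delta=0.0)) == list(ps.labels)

    def test_retained_fraction_half(self):
        labels = apply_unknown_threshold(prob_series([0.4, 0.9]), delta=0.5)
        assert (labels != UNKNOWN).mean() == 0.5


class TestSweepDelta:
    def test_delta_zero_recovers_raw_accuracy(self):
        ps = prob_series([0.3, 0.6, 0.9])
        truth = np.array(["descending_stairs", "walking", "descending_stairs"], dtype=object)
        out = sweep_delta(ps, truth, [0.0])
        assert out.loc[0, "retained_fraction"] == 1.0
        assert out.loc[0, "accuracy"] == pytest.approx(2 / 3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_retained_fraction_monotone_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(7), size=30)
        ps = ProbSeries(pd.DataFrame(p, columns=list(ACTIVITIES)), np.arange(30))
        truth = rng.choice(ACTIVITIES, size=30)
        deltas = np.linspace(0, 1, 101)
        out = sweep_delta(ps, truth, deltas)
        # brute-force oracle: count retained seconds by explicit comparison
        brute = [(ps.p_max >= d).sum() / 30 for d in deltas]
        assert np.allclose(out["retained_fraction"], brute)
        assert (np.diff(out["retained_fraction"]) <= 1e-12).all()

    def test_nothing_retained_gives_nan_accuracy(self):
        ps = prob_series([0.4, 0.45])
        out = sweep_delta(ps, np.array(["walking", "walking"], dtype=object), [0.99])
        assert out.loc[0, "retained_fraction"] == 0.0
        assert np.isnan(out.loc[0, "accuracy"])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sweep_delta(prob_series([0.5]), np.array(["walking"], dtype=object), [])


class TestStationaryRule:
    def test_resting_window_overrides_classifier(self):
        windows = [sine_window(0, amplitude=0.0), sine_window(2.0, amplitude=2.0)]
        labels = pd.Series(["walking", "walking"], dtype=object)
        out = apply_stationary_rule(windows, labels)
        assert list(out) == [SITTING_OR_STANDING, "walking"]

    def test_threshold_boundary(self):
        rng = np.random.default_rng(0)
        low = Window(0, 9.81 + rng.normal(0, np.sqrt(0.05), 150), np.zeros(150), np.zeros(150))
        assert np.var(low.rx) < 0.1
        out = apply_stationary_rule([low], pd.Series(["jogging"], dtype=object))
        assert out.iloc[0] == SITTING_OR_STANDING

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            apply_stationary_rule([sine_window(1)], pd.Series(["walking", "walking"], dtype=object))


class TestEstimateCadence:
    def test_pure_tone_recovered_within_bin(self):
        w = sine_window(2.0, amplitude=2.0)
        assert estimate_cadence(w) == pytest.approx(2.0, abs=50 / 512)

    def test_constant_window_has_no_cadence(self):
        assert estimate_cadence(sine_window(0, amplitude=0.0)) == 0.0

    def test_noisy_tone_recovered_reliably(self):
        # SNR 10 in power: amplitude = noise_sd * sqrt(20)
        hits = 0
        for seed in range(100):
            w = sine_window(1.5, amplitude=0.5 * np.sqrt(20), noise_sd=0.5, seed=seed)
            if abs(estimate_cadence(w) - 1.5) <= 50 / 512 + 1e-9:
                hits += 1
        assert hits >= 95

    def test_band_limits_respected(self):
        # an 8 Hz tone lies outside the physiological band -> no cadence
        assert estimate_cadence(sine_window(8.0, amplitude=2.0)) == 0.0


class TestCountCycles:
    def test_constant_cadence_sums_over_seconds(self):
        spec = get_spec("walking")
        spec.cadence, spec.noise_sd = 2.0, 0.0
        ws = windows_from_recording(synth_activity(spec, 60, seed=0))
        labels = pd.Series(["walking"] * len(ws), dtype=object)
        counts = count_cycles(labels, ws)
        assert counts.cycles["walking"] == pytest.approx(2.0 * len(ws), rel=0.05)
        assert counts.seconds == {"walking": len(ws)}

    def test_all_unknown_counts_nothing(self):
        ws = [sine_window(2.0)] * 10
        counts = count_cycles(pd.Series([UNKNOWN] * 10, dtype=object), ws)
        assert counts.cycles == {}
        assert counts.seconds == {UNKNOWN: 10}

    def test_transition_runs_counted_once_each(self):
        ws = [sine_window(0, amplitude=1.0)] * 9
        labels = pd.Series(
            ["sit_to_stand", UNKNOWN, "sit_to_stand", "sit_to_stand", UNKNOWN,
             UNKNOWN, "sit_to_stand", UNKNOWN, UNKNOWN], dtype=object)
        counts = count_cycles(labels, ws)
        assert counts.cycles["sit_to_stand"] == 3.0
        raw = count_cycles(labels, ws, PostprocessConfig(transitions_as_window_count=True))
        assert raw.cycles["sit_to_stand"] == 4.0

    def test_additive_over_concatenation(self):
        spec = get_spec("walking")
        ws = windows_from_recording(synth_activity(spec, 30, seed=1))
        labels = pd.Series(["walking"] * len(ws), dtype=object)
        whole = count_cycles(labels, ws)
        half = count_cycles(labels[:10], ws[:10]) + count_cycles(labels[10:].reset_index(drop=True), ws[10:])
        assert half.cycles["walking"] == pytest.approx(whole.cycles["walking"])
        assert half.seconds == whole.seconds

    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="vocabulary"):
            count_cycles(pd.Series(["napping"], dtype=object), [sine_window(1)])


def test_rule_order_stationary_overrides_reject():
    """A resting second is sitting_or_standing even when the model was confident."""
    from jolo.postprocess import postprocess_labels
    ps = prob_series([0.99, 0.3])
    windows = [sine_window(0, amplitude=0.0), sine_window(2.0, amplitude=2.0)]
    out = postprocess_labels(ps, windows, PostprocessConfig(delta=0.5))
    assert list(out) == [SITTING_OR_STANDING, UNKNOWN]
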