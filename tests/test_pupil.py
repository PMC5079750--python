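"""Blink handling, filtering, artifact screens, and epoching for pupil data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaphysio import (
    EpochMatrix,
    PhysioTimeSeries,
    PupilPreprocessor,
    blink_fraction_per_trial,
    detect_blinks_and_interpolate,
    epoch_and_baseline,
    preprocess_pupil_trials,
)


def _series(samples, fs=100.0):
    return PhysioTimeSeries(np.asarray(samples, float), fs=fs, channel="pupil_au")


class TestBlinkInterpolation:
    def test_clean_trace_unchanged(self):
        x = 3000 + 50 * np.sin(np.linspace(0, 10, 500))
        out, mask = detect_blinks_and_interpolate(_series(x))
        np.testing.assert_array_equal(out.samples, x)
        assert not mask.any()

    def test_interior_gap_becomes_linear_ramp(self):
        out, mask = detect_blinks_and_interpolate(_series([800, 400, 400, 900]))
        np.testing.assert_allclose(out.samples, [800, 800 + 100 / 3, 800 + 200 / 3, 900])
        assert mask.tolist() == [False, True, True, False]

    def test_boundary_blink_extends_nearest_reliable_sample(self):
        out, _ = detect_blinks_and_interpolate(_series([100, 100, 900, 950, 200]))
        np.testing.assert_allclose(out.samples, [900, 900, 900, 950, 950])

    def test_all_blink_recording_rejected(self):
        with pytest.raises(ValueError):
            detect_blinks_and_interpolate(_series(np.full(100, 10.0)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_preserves_reliable_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = 3000 + 200 * rng.standard_normal(300)
        idx = rng.integers(0, 300, size=10)
        x[idx] = 50.0
        once, mask = detect_blinks_and_interpolate(_series(x))
        twice, mask2 = detect_blinks_and_interpolate(once)
        np.testing.assert_array_equal(once.samples, twice.samples)
        assert not mask2.any()
        np.testing.assert_array_equal(once.samples[~mask], x[~mask])


class TestPreprocessor:
    @staticmethod
    def _epochs(data, fs=100.0):
        n = data.shape[1]
        start_ms = -500.0
        end_ms = start_ms + (n - 1) / fs * 1000
        return EpochMatrix(
            data=data, fs=fs, window=(start_ms, end_ms), baseline_window=(-500.0, 0.0),
            trial_index=np.arange(data.shape[0]),
        )

    def test_constant_trials_become_all_zero(self):
        epochs = self._epochs(np.full((5, 400), 3000.0))
        out = preprocess_pupil_trials(epochs)
        np.testing.assert_allclose(out.data[~out.rejected], 0.0, atol=1e-9)

    def test_step_discontinuity_trial_rejected_by_derivative_rule(self, rng):
        data = 3000 + 5 * rng.standard_normal((100, 400))
        data[17, 200:] += 800.0  # step artifact
        epochs = self._epochs(data)
        out = preprocess_pupil_trials(epochs)
        assert out.rejected[17] and out.reject_reason[17] == "derivative"
        assert out.rejected.sum() <= 5

    def test_50hz_sinusoid_attenuated_20db(self):
        fs = 500.0
        t = np.arange(0, 2, 1 / fs)
        data = np.tile(np.sin(2 * np.pi * 50 * t), (4, 1))
        epochs = EpochMatrix(
            data=data.copy(), fs=fs, window=(0.0, (len(t) - 1) / fs * 1000),
            baseline_window=(0.0, 100.0), trial_index=np.arange(4),
        )
        out = PupilPreprocessor(derivative_sd=1e9).fit(epochs).transform(epochs)
        mid = slice(200, 800)  # avoid filter edge effects
        ratio = np.abs(out.data[0, mid]).max() / np.abs(data[0, mid]).max()
        assert ratio < 0.1  # >= 20 dB attenuation

    def test_blink_fraction_rejection(self):
        epochs = self._epochs(np.full((4, 400), 3000.0))
        fracs = np.array([0.0, 0.1, 0.3, 0.9])
        out = preprocess_pupil_trials(epochs, blink_fractions=fracs)
        assert out.rejected.tolist() == [False, False, True, True]
        assert out.reject_reason[2] == "blink_fraction"

    def test_low_sampling_rate_rejected(self):
        epochs = self._epochs(np.full((3, 50), 3000.0), fs=50.0)
        with pytest.raises(ValueError, match="low-pass"):
            preprocess_pupil_trials(epochs)

    def test_rejection_bookkeeping_conserves_trials(self, rng):
        data = 3000 + 5 * rng.standard_normal((50, 400))
        data[3, 200:] += 900.0
        epochs = self._epochs(data)
        out = preprocess_pupil_trials(
            epochs, blink_fractions=np.where(np.arange(50) < 5, 0.5, 0.0)
        )
        report = out.rejection_report()
        assert report["kept"] + sum(
            v for k, v in report.items() if k not in ("kept", "total")
        ) == report["total"] == 50


class TestEpoching:
    def test_constant_series_epochs_to_zero(self):
        series = _series(np.full(5000, 2500.0))
        out = epoch_and_baseline(series, [10.0, 20.0], (-500, 2000), (-500, 0))
        np.testing.assert_allclose(out.data, 0.0)

    def test_impulse_lands_at_expected_column(self):
        x = np.zeros(5000)
        x[200] = 7.0  # 1 s after a 1.0 s onset at fs=100
        series = _series(x)
        out = epoch_and_baseline(series, [1.0], (0, 3000), (0, 0))
        t = out.times_ms
        assert out.data[0, np.argmin(np.abs(t - 1000))] == pytest.approx(7.0)

    def test_edge_onsets_marked_partial_not_truncated(self):
        series = _series(np.full(1000, 1.0))
        out = epoch_and_baseline(series, [0.1, 5.0, 9.9], (-500, 2000), (-500, 0))
        assert out.rejected.tolist() == [True, False, True]
        assert out.reject_reason[0] == "partial_epoch"

    def test_window_must_cover_baseline(self):
        with pytest.raises(ValueError):
            epoch_and_baseline(_series(np.ones(100)), [0.5], (0, 500), (-500, 0))

    def test_blink_fraction_alignment(self):
        mask = np.zeros(5000, dtype=bool)
        mask[200:300] = True  # 2.0-3.0 s blink at fs=100
        series = _series(np.full(5000, 3000.0))
        epochs = epoch_and_baseline(series, [2.0, 30.0], (0, 1000), (0, 0))
        fr = blink_fraction_per_trial(mask, epochs, onsets=np.array([2.0, 30.0]))
        assert fr[0] > 0.9 and fr[1] == 0.0
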