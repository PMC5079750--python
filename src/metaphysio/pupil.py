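"""Pupillometry preprocessing.

Order of operations mirrors standard pupillometry practice for this task:
blink detection and linear interpolation on the continuous trace, epoching
around the trial-onset mask, rejection of trials that were mostly blink,
per-trial linear detrending, zero-phase low-pass filtering, a
first-derivative artifact screen, and pre-stimulus baseline correction.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .timeseries import EpochMatrix, PhysioTimeSeries

__all__ = [
    "detect_blinks_and_interpolate",
    "blink_fraction_per_trial",
    "PupilPreprocessor",
    "preprocess_pupil_trials",
]


def detect_blinks_and_interpolate(
    pupil: PhysioTimeSeries, threshold: float = 600.0
) -> tuple[PhysioTimeSeries, np.ndarray]:
    """Detect blinks as sub-threshold samples and linearly interpolate them.

    Every sample with amplitude below ``threshold`` (arbitrary units) is
    treated as part of a blink.  Interior blink runs are replaced by a
    linear ramp between the flanking reliable samples; runs touching the
    start or end of the recording are filled with the nearest reliable
    value.  Supra-threshold samples are left bit-identical, which makes the
    operation idempotent.

    Returns the cleaned series and the boolean blink mask.
    """
    if pupil.channel != "pupil_au":
        raise ValueError("expected a pupil_au channel")
    x = pupil.samples
    mask = x < threshold
    cleaned = x.copy()
    if mask.all():
        raise ValueError("entire recording below blink threshold")
    if mask.any():
        idx = np.arange(len(x))
        good = ~mask
        cleaned[mask] = np.interp(idx[mask], idx[good], x[good])
    out = PhysioTimeSeries(cleaned, fs=pupil.fs, t0=pupil.t0, channel=pupil.channel)
    return out, mask


def blink_fraction_per_trial(
    mask: np.ndarray, epochs: EpochMatrix, t0: float = 0.0, onsets: np.ndarray | None = None
) -> np.ndarray:
    """Fraction of blink samples within each trial's epoch window.

    ``mask`` is the continuous blink mask; epochs define the windows via
    their onsets (required) and window/fs metadata.
    """
    if onsets is None:
        raise ValueError("onsets are required to map epochs onto the mask")
    onsets = np.asarray(onsets, dtype=float)
    n_samples = epochs.data.shape[1]
    fracs = np.zeros(len(onsets))
    start_idx = np.round((onsets - t0 + epochs.window[0] / 1000.0) * epochs.fs).astype(int)
    for i, s0 in enumerate(start_idx):
        s0c, s1c = max(s0, 0), min(s0 + n_samples, len(mask))
        if s1c <= s0c:
            fracs[i] = 1.0
            continue
        fracs[i] = float(mask[s0c:s1c].mean())
    return fracs


class PupilPreprocessor(BaseEstimator, TransformerMixin):
    """Per-trial detrend, low-pass filter, derivative screen, and baseline.

    Parameters
    ----------
    lowpass_hz : float
        Low-pass cut-off (Hz); applied as a zero-phase 4th-order Butterworth
        (filtfilt).  Requires fs > 2 * lowpass_hz.
    filter_order : int
        Butterworth order (applied forward-backward, so effective 2x).
    derivative_sd : float
        Trials whose max |first derivative| exceeds the across-trial mean by
        more than this many SDs are rejected (artifact "pupil-lock" screen).
    blink_reject_fraction : float
        Trials with more than this fraction of blink samples are rejected.

    The transformer consumes and returns :class:`EpochMatrix`; rejection
    flags accumulate on the object.  ``fit`` is stateless (kept for sklearn
    pipeline compatibility).
    """

    def __init__(
        self,
        lowpass_hz: float = 30.0,
        filter_order: int = 4,
        derivative_sd: float = 3.0,
        blink_reject_fraction: float = 0.25,
    ):
        self.lowpass_hz = lowpass_hz
        self.filter_order = filter_order
        self.derivative_sd = derivative_sd
        self.blink_reject_fraction = blink_reject_fraction

    def fit(self, X: EpochMatrix, y=None):  # noqa: N803 - sklearn signature
        self.n_features_in_ = X.data.shape[1]
        return self

    def transform(self, X: EpochMatrix, blink_fractions: np.ndarray | None = None) -> EpochMatrix:
        epochs = X
        if epochs.fs <= 2 * self.lowpass_hz:
            raise ValueError(
                f"sampling rate {epochs.fs} Hz too low for a {self.lowpass_hz} Hz low-pass"
            )
        if blink_fractions is not None:
            epochs.reject(
                np.asarray(blink_fractions) > self.blink_reject_fraction, "blink_fraction"
            )
        ok = ~epochs.rejected
        if ok.any():
            data = epochs.data[ok]
            data = signal.detrend(data, axis=1, type="linear")
            sos = signal.butter(
                self.filter_order, self.lowpass_hz, btype="low", fs=epochs.fs, output="sos"
            )
            data = signal.sosfiltfilt(sos, data, axis=1)
            epochs.data[ok] = data
        # derivative artifact screen (computed on the filtered data)
        deriv_max = np.full(epochs.n_trials, np.nan)
        ok = ~epochs.rejected
        deriv_max[ok] = np.abs(np.diff(epochs.data[ok], axis=1)).max(axis=1) * epochs.fs
        mu, sd = np.nanmean(deriv_max[ok]), np.nanstd(deriv_max[ok])
        if sd > 0:
            epochs.reject(
                np.nan_to_num(deriv_max, nan=-np.inf) > mu + self.derivative_sd * sd,
                "derivative",
            )
        _baseline(epochs)
        return epochs


def _baseline(epochs: EpochMatrix) -> None:
    t = epochs.times_ms
    b0, b1 = epochs.baseline_window
    sel = (t >= b0) & (t <= b1)
    ok = ~epochs.rejected
    epochs.data[ok] -= np.nanmean(epochs.data[ok][:, sel], axis=1, keepdims=True)


def preprocess_pupil_trials(
    epochs: EpochMatrix,
    blink_fractions: np.ndarray | None = None,
    lowpass_hz: float = 30.0,
    derivative_sd: float = 3.0,
    blink_reject_fraction: float = 0.25,
) -> EpochMatrix:
    """Functional wrapper over :class:`PupilPreprocessor`."""
    proc = PupilPreprocessor(
        lowpass_hz=lowpass_hz,
        derivative_sd=derivative_sd,
        blink_reject_fraction=blink_reject_fraction,
    )
    return proc.fit(epochs).transform(epochs, blink_fractions=blink_fractions)
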