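"""Continuous physiological time series and trial epoch containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhysioTimeSeries", "EpochMatrix", "epoch_and_baseline"]


@dataclass
class PhysioTimeSeries:
    """A uniformly sampled physiological signal.

    samples : signal values (pupil a.u., ECG mV, or HR bpm)
    fs : sampling rate, Hz
    t0 : absolute time of the first sample, seconds
    channel : one of {"pupil_au", "ecg_mv", "hr_bpm"}
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel: str = "pupil_au"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.channel not in ("pupil_au", "ecg_mv", "hr_bpm"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class EpochMatrix:
    """Trials x samples matrix of a baseline-corrected signal.

    data : (n_trials, n_samples) array
    fs : sampling rate, Hz
    window : (start_ms, end_ms) relative to the trial-locking event
    baseline_window : (start_ms, end_ms) used for baseline subtraction
    trial_index : original trial indices, one per row
    rejected : per-trial rejection flag
    reject_reason : reason string per trial ("" if kept)
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    baseline_window: tuple[float, float]
    trial_index: np.ndarray
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        n = self.data.shape[0]
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [""] * n
        if not (
            self.window[0] <= self.baseline_window[0]
            and self.baseline_window[1] <= self.window[1]
        ):
            raise ValueError("window must cover baseline_window")

    @property
    def times_ms(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.fs * 1000.0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self) -> np.ndarray:
        """Data rows of retained (non-rejected) trials."""
        return self.data[~self.rejected]

    def reject(self, mask: np.ndarray, reason: str) -> None:
        """Mark trials rejected, recording a reason for the first rule hit."""
        mask = np.asarray(mask, dtype=bool)
        for i in np.nonzero(mask & ~self.rejected)[0]:
            self.reject_reason[i] = reason
        self.rejected |= mask

    def rejection_report(self) -> dict[str, int]:
        """Per-reason rejection counts plus kept/total bookkeeping."""
        report: dict[str, int] = {}
        for reason in self.reject_reason:
            if reason:
                report[reason] = report.get(reason, 0) + 1
        report["kept"] = int((~self.rejected).sum())
        report["total"] = int(self.n_trials)
        return report


def epoch_and_baseline(
    series: PhysioTimeSeries,
    onsets: np.ndarray,
    window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> EpochMatrix:
    """Slice a continuous series into trial epochs and baseline-correct.

    Parameters
    ----------
    series : PhysioTimeSeries
    onsets : trial-locking event times, seconds (absolute)
    window : (start_ms, end_ms) epoch relative to each onset
    baseline_window : (start_ms, end_ms); its per-trial mean is subtracted

    Trials whose epoch would extend beyond the recording are marked rejected
    (reason ``partial_epoch``) with a row of NaNs rather than silently
    truncated.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    n_samples = int(round((window[1] - window[0]) / 1000.0 * series.fs)) + 1
    offsets = np.arange(n_samples)
    start_idx = np.round((onsets - series.t0 + window[0] / 1000.0) * series.fs).astype(int)
    data = np.full((len(onsets), n_samples), np.nan)
    rejected = np.zeros(len(onsets), dtype=bool)
    reasons = [""] * len(onsets)
    for i, s0 in enumerate(start_idx):
        if s0 < 0 or s0 + n_samples > len(series.samples):
            rejected[i] = True
            reasons[i] = "partial_epoch"
            continue
        data[i] = series.samples[s0 + offsets]
    epochs = EpochMatrix(
        data=data,
        fs=series.fs,
        window=window,
        baseline_window=baseline_window,
        trial_index=np.arange(len(onsets)),
        rejected=rejected,
        reject_reason=reasons,
    )
    _subtract_baseline(epochs)
    return epochs


def _subtract_baseline(epochs: EpochMatrix) -> None:
    t = epochs.times_ms
    b0, b1 = epochs.baseline_window
    sel = (t >= b0) & (t <= b1)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    ok = ~epochs.rejected
    epochs.data[ok] -= np.nanmean(epochs.data[ok][:, sel], axis=1, keepdims=True)
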