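"""Cardiac preprocessing: QRS detection, artifact flags, instantaneous HR.

R-peaks are detected with the Pan-Tompkins algorithm (band-pass,
derivative, squaring, moving-window integration, adaptive dual thresholds
with search-back) after resampling the ECG to 200 Hz, the rate the
algorithm's constants were designed for.  Interbeat intervals are converted
to instantaneous heart rate (60/IBI, assigned at beat midpoints), cubic
spline interpolated, and resampled on a uniform 10 Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .timeseries import PhysioTimeSeries

__all__ = [
    "CardiacSeries",
    "detect_qrs_pan_tompkins",
    "flag_cardiac_artifacts",
    "compute_instantaneous_hr",
]

_PT_FS = 200.0  # Hz, operating rate of the Pan-Tompkins stages


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def detect_qrs_pan_tompkins(ecg: PhysioTimeSeries) -> np.ndarray:
    """Detect R-peaks; returns sample indices into the original series.

    Stages: polyphase resampling to 200 Hz; 5-15 Hz band-pass (zero-phase
    Butterworth); five-point derivative; squaring; 150 ms moving-window
    integration; adaptive signal/noise thresholds with a half-threshold
    search-back when an expected beat is missed.  Detected peaks are refined
    to the band-passed R-wave maximum and reported at the original sampling
    resolution.
    """
    if ecg.channel != "ecg_mv":
        raise ValueError("expected an ecg_mv channel")
    if ecg.duration < 5.0:
        raise ValueError("need >= 5 s of ECG for threshold learning")
    x = _resample_to(ecg.samples, ecg.fs, _PT_FS)
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no peaks detected", stacklevel=2)
        return np.array([], dtype=int)

    sos = signal.butter(2, [5.0, 15.0], btype="band", fs=_PT_FS, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (_PT_FS / 8.0), mode="same")
    sq = deriv**2
    win = int(round(0.150 * _PT_FS))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * _PT_FS))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        warnings.warn("no candidate peaks in integrated signal", stacklevel=2)
        return np.array([], dtype=int)

    # threshold learning on the first two seconds
    learn = mwi[: int(2 * _PT_FS)]
    spki = 0.25 * learn.max()
    npki = 0.5 * learn.mean()
    qrs: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < len(cand):
        p = cand[i]
        if mwi[p] > threshold():
            if qrs and p - qrs[-1] < refractory:
                i += 1
                continue
            qrs.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(qrs) > 1:
                rr_history.append(qrs[-1] - qrs[-2])
                rr_history[:] = rr_history[-8:]
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back: expected beat overdue -> accept at half threshold
            if qrs and rr_history:
                rr_avg = float(np.mean(rr_history))
                if p - qrs[-1] > 1.66 * rr_avg and mwi[p] > 0.5 * threshold():
                    qrs.append(p)
                    spki = 0.25 * mwi[p] + 0.75 * spki
                    rr_history.append(qrs[-1] - qrs[-2])
                    rr_history[:] = rr_history[-8:]
        i += 1

    # refine: MWI peaks lag the R wave; take the band-passed maximum in a
    # window ending at the integrator peak
    half = int(round(0.150 * _PT_FS))
    refined = []
    for p in qrs:
        lo, hi = max(p - half, 0), min(p + int(0.050 * _PT_FS), len(bp))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    # map back to original sampling grid
    return np.round(refined / _PT_FS * ecg.fs).astype(int)


def flag_cardiac_artifacts(
    rpeak_times: np.ndarray,
    duration: float | None = None,
    segment_len: float = 30.0,
    hr_bounds: tuple[float, float] = (50.0, 120.0),
    ibi_bounds: tuple[float, float] = (0.45, 1.40),
) -> dict:
    """Flag segments and beats for manual inspection.

    30-s segments are flagged when their mean heart rate falls outside
    ``hr_bounds`` (bpm); individual beats are flagged when either adjacent
    interbeat interval falls outside ``ibi_bounds`` (s).  Returns a dict
    with ``segment_flags`` (bool per segment), ``beat_flags`` (bool per
    beat), and ``ibi_flags`` (bool per IBI).
    """
    rpeak_times = np.asarray(rpeak_times, dtype=float)
    ibis = np.diff(rpeak_times)
    ibi_flags = (ibis < ibi_bounds[0]) | (ibis > ibi_bounds[1])
    beat_flags = np.zeros(len(rpeak_times), dtype=bool)
    bad = np.nonzero(ibi_flags)[0]
    beat_flags[bad] = True
    beat_flags[bad + 1] = True

    if duration is None:
        duration = float(rpeak_times[-1]) if len(rpeak_times) else 0.0
    n_seg = max(int(np.ceil(duration / segment_len)), 1)
    segment_flags = np.zeros(n_seg, dtype=bool)
    mids = rpeak_times[:-1] + ibis / 2.0
    for s in range(n_seg):
        in_seg = (mids >= s * segment_len) & (mids < (s + 1) * segment_len)
        if not in_seg.any():
            segment_flags[s] = True
            continue
        mean_hr = 60.0 / float(np.mean(ibis[in_seg]))
        segment_flags[s] = not (hr_bounds[0] <= mean_hr <= hr_bounds[1])
    return {
        "segment_flags": segment_flags,
        "beat_flags": beat_flags,
        "ibi_flags": ibi_flags,
    }


@dataclass
class CardiacSeries:
    """R-peak train with its derived 10 Hz instantaneous-HR series."""

    rpeak_times: np.ndarray
    ibis: np.ndarray
    hr_10hz: PhysioTimeSeries
    spline: CubicSpline


def compute_instantaneous_hr(
    rpeak_times: np.ndarray,
    fs_out: float = 10.0,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> CardiacSeries:
    """Instantaneous heart rate on a uniform grid.

    HR = 60/IBI is assigned at interbeat midpoints, cubic-spline
    interpolated, and sampled at ``fs_out`` Hz over
    ``[t_start, t_end]`` (default: up to the last R-peak).  The spline is
    never extrapolated: times outside the first/last midpoint take the
    edge value.
    """
    rpeak_times = np.asarray(rpeak_times, dtype=float)
    if len(rpeak_times) < 4:
        raise ValueError("need >= 4 beats for cubic spline interpolation")
    if np.any(np.diff(rpeak_times) <= 0):
        raise ValueError("rpeak_times must be strictly increasing")
    ibis = np.diff(rpeak_times)
    mids = rpeak_times[:-1] + ibis / 2.0
    hr = 60.0 / ibis
    spline = CubicSpline(mids, hr)
    if t_end is None:
        t_end = float(rpeak_times[-1])
    grid = np.arange(t_start, t_end + 0.5 / fs_out, 1.0 / fs_out)
    values = spline(np.clip(grid, mids[0], mids[-1]))
    series = PhysioTimeSeries(values, fs=fs_out, t0=t_start, channel="hr_bpm")
    return CardiacSeries(rpeak_times=rpeak_times, ibis=ibis, hr_10hz=series, spline=spline)
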