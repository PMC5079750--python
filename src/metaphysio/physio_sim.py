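"""Synthetic pupil and cardiac traces with known trial-wise effects.

Evoked responses are built by superposing a stereotyped impulse-response
kernel at each trial onset, with the per-trial amplitude given by a linear
combination ``base + beta . x`` of the (z-scored) trial regressors — the
same regressors the analysis-side GLM estimates — so injected betas are the
ground truth for parameter-recovery tests.  The pupil kernel is the
classic Erlang/gamma-shaped pupillary impulse response (time-to-peak
~0.93 s); the cardiac kernel is a gamma-shaped heart-rate deceleration.
R-peaks are produced by integrate-and-fire on the instantaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import build_design_matrix
from .timeseries import PhysioTimeSeries

__all__ = [
    "TrialTimeline",
    "PhysioGenParams",
    "pupil_irf",
    "hr_kernel",
    "trial_amplitudes",
    "simulate_pupil_trace",
    "simulate_rpeak_train",
    "synthesize_ecg",
]


@dataclass(frozen=True)
class TrialTimeline:
    """Within-trial event timing, milliseconds from forward-mask onset."""

    forward_mask_on: float = 0.0
    forward_mask_dur: float = 250.0
    cue_dur: float = 1000.0 / 60.0  # one 60 Hz frame, ~16.667 ms
    neutral_mask_dur: float = 100.0
    static_dots_dur: float = 250.0
    motion_dur: float = 250.0
    choice_window: float = 800.0
    rating_dur: float = 2500.0
    iti_range: tuple[float, float] = (2000.0, 3000.0)

    @property
    def trial_length_ms(self) -> float:
        """Mask onset to rating offset (epoch end)."""
        return (
            self.forward_mask_dur
            + self.cue_dur
            + self.neutral_mask_dur
            + self.static_dots_dur
            + self.motion_dur
            + self.choice_window
            + self.rating_dur
        )

    def onsets(self, n_trials: int, rng: np.random.Generator, t_first: float = 10.0) -> np.ndarray:
        """Trial onset times (s) with the jittered inter-trial interval."""
        itis = rng.uniform(*self.iti_range, size=n_trials) / 1000.0
        gaps = self.trial_length_ms / 1000.0 + itis
        return t_first + np.concatenate([[0.0], np.cumsum(gaps[:-1])])


@dataclass
class PhysioGenParams:
    """Ground-truth parameters of the physiological generator.

    pupil/hr ``effect_betas`` map regressor names (see
    :data:`metaphysio.glm.REGRESSORS`) to evoked-amplitude modulations in
    a.u. (pupil) or bpm (heart rate), applied per 1 SD of the z-scored
    regressor.  Defaults inject the qualitative pattern of interest: noise
    dilates the pupil, disgust cues dilate it further, and the cue x noise
    interaction is negative (cues reverse the dilatory effect of noise);
    confidence and cue accelerate the heart with a negative
    cue x confidence interaction.
    """

    # pupil
    pupil_baseline: float = 3000.0  # a.u.
    pupil_amp: float = 200.0  # grand-mean evoked amplitude, a.u.
    pupil_betas: dict[str, float] = field(
        default_factory=lambda: {"noise": 25.0, "cue": 20.0, "confidence": 10.0, "cue_x_noise": -20.0}
    )
    pupil_noise_sd: float = 30.0  # a.u.
    pupil_irf_tpeak: float = 0.93  # s, kernel time-to-peak
    pupil_irf_shape: float = 10.1  # Erlang shape parameter
    pupil_onset_delay: float = 1.15  # s, cascade delay so grand-mean peaks ~2.1 s
    blink_rate: float = 0.3  # blinks per trial
    blink_dur: float = 0.15  # s
    blink_value: float = 100.0  # a.u., well below the 600 a.u. threshold
    # cardiac
    baseline_hr: float = 65.0  # bpm
    hr_amp: float = -3.0  # grand-mean evoked deceleration, bpm
    hr_betas: dict[str, float] = field(
        default_factory=lambda: {"confidence": 0.3, "cue": 0.3, "cue_x_confidence": -0.3}
    )
    hr_noise_sd: float = 0.5  # bpm (slow rate noise)
    hr_kernel_trough: float = 1.9  # s post-onset
    ectopic_rate: float = 0.0  # ectopic beats per minute

    def __post_init__(self) -> None:
        if self.pupil_noise_sd < 0 or self.hr_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (40.0 < self.baseline_hr < 140.0):
            raise ValueError("baseline_hr must be in (40, 140) bpm")


def pupil_irf(
    t: np.ndarray, tpeak: float = 0.93, shape: float = 10.1, delay: float = 0.0
) -> np.ndarray:
    """Erlang/gamma pupillary impulse response, unit peak amplitude.

    ``h(t) = (t/tpeak)^shape * exp(shape * (1 - t/tpeak))`` for t > delay
    (time measured from ``delay``), 0 before.
    """
    t = np.asarray(t, dtype=float) - delay
    h = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / tpeak
    h[pos] = r**shape * np.exp(shape * (1.0 - r))
    return h


def hr_kernel(t: np.ndarray, trough: float = 1.9, shape: float = 4.0) -> np.ndarray:
    """Gamma-shaped evoked heart-rate kernel, unit (positive) peak at ``trough``.

    Multiply by a negative amplitude for the canonical deceleration.
    """
    return pupil_irf(t, tpeak=trough, shape=shape)


def trial_amplitudes(
    trials, base: float, betas: dict[str, float], include_cue_by_noise: bool = True
) -> np.ndarray:
    """Per-trial evoked amplitudes ``base + beta . x`` on z-scored regressors."""
    n = len(trials) if trials is not None else 0
    if not betas:
        return np.full(n, float(base))
    design = build_design_matrix(trials, include_cue_by_noise=include_cue_by_noise)
    amp = np.full(len(trials), float(base))
    for name, b in betas.items():
        if name not in design.X.columns:
            raise ValueError(f"unknown regressor {name!r} in effect betas")
        amp += b * design.X[name].to_numpy()
    return amp


def _superpose(
    t: np.ndarray, onsets: np.ndarray, amplitudes: np.ndarray, kernel
) -> np.ndarray:
    """Sum amplitude-scaled kernels at each onset (kernel support 8 s).

    Onsets are snapped to the sampling grid so the evoked shape is
    identical across trials (sub-sample onset phase is below the
    instrument's resolution anyway).
    """
    out = np.zeros_like(t)
    fs = 1.0 / (t[1] - t[0])
    support = int(round(8.0 * fs))
    onsets = np.round(np.asarray(onsets) * fs) / fs
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(np.searchsorted(t, onset - 0.25 / fs))
        i1 = min(i0 + support, len(t))
        if i0 >= len(t):
            continue
        out[i0:i1] += amp * kernel(t[i0:i1] - onset)
    return out


def simulate_pupil_trace(
    trials,
    onsets: np.ndarray,
    physio: PhysioGenParams | None = None,
    fs: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    duration: float | None = None,
) -> tuple[PhysioTimeSeries, np.ndarray]:
    """Continuous pupil trace for one subject's trial sequence.

    trace = baseline + sum_i amp_i * IRF(t - onset_i) + noise, with blinks
    injected as brief excursions to ``blink_value`` (below the detection
    threshold).  Returns the series and the ground-truth blink mask.
    """
    physio = physio or PhysioGenParams()
    rng = np.random.default_rng(seed)
    onsets = np.asarray(onsets, dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("trial onsets must be strictly increasing")
    if np.any(np.diff(onsets) < 6.0):
        import warnings

        warnings.warn("inter-trial spacing < 6 s: evoked responses overlap", stacklevel=2)
    if duration is None:
        duration = float(onsets[-1]) + 8.0
    t = np.arange(0.0, duration, 1.0 / fs)
    amps = trial_amplitudes(trials, physio.pupil_amp, physio.pupil_betas)

    def kern(tau):
        return pupil_irf(
            tau, tpeak=physio.pupil_irf_tpeak, shape=physio.pupil_irf_shape,
            delay=physio.pupil_onset_delay,
        )

    trace = physio.pupil_baseline + _superpose(t, onsets, amps, kern)
    if physio.pupil_noise_sd > 0:
        trace = trace + physio.pupil_noise_sd * rng.standard_normal(len(t))

    blink_mask = np.zeros(len(t), dtype=bool)
    n_blinks = rng.poisson(physio.blink_rate * len(onsets))
    if n_blinks and physio.blink_rate > 0:
        starts = rng.uniform(0.0, duration - physio.blink_dur, size=n_blinks)
        w = int(round(physio.blink_dur * fs))
        for s in starts:
            i0 = int(round(s * fs))
            blink_mask[i0 : i0 + w] = True
        trace = trace.copy()
        trace[blink_mask] = physio.blink_value
    return PhysioTimeSeries(trace, fs=fs, t0=0.0, channel="pupil_au"), blink_mask


def simulate_rpeak_train(
    trials,
    onsets: np.ndarray,
    physio: PhysioGenParams | None = None,
    seed: int | np.random.Generator | None = None,
    duration: float | None = None,
    dt: float = 0.01,
) -> tuple[np.ndarray, PhysioTimeSeries]:
    """R-peak times from an integrate-and-fire model of instantaneous rate.

    The instantaneous rate is ``baseline_hr + sum_i amp_i * K(t - onset_i)``
    (bpm) plus slow Gaussian noise; a beat fires whenever the integral of
    rate/60 crosses the next integer.  Returns the peak times (s) and the
    ground-truth rate series.
    """
    physio = physio or PhysioGenParams()
    rng = np.random.default_rng(seed)
    onsets = np.asarray(onsets, dtype=float)
    if duration is None:
        duration = float(onsets[-1]) + 8.0 if len(onsets) else 60.0
    t = np.arange(0.0, duration, dt)
    if len(onsets):
        amps = trial_amplitudes(trials, physio.hr_amp, physio.hr_betas)
        rate = physio.baseline_hr + _superpose(
            t, onsets, amps, lambda tau: hr_kernel(tau, trough=physio.hr_kernel_trough)
        )
    else:
        rate = np.full_like(t, physio.baseline_hr)
    if physio.hr_noise_sd > 0:
        # slow rate fluctuations: smoothed white noise (~0.5 Hz bandwidth)
        raw = rng.standard_normal(len(t))
        w = max(int(round(2.0 / dt)), 1)
        kernel = np.ones(w) / w
        slow = np.convolve(raw, kernel, mode="same")
        slow *= physio.hr_noise_sd / max(slow.std(), 1e-12)
        rate = rate + slow
    if np.any(rate <= 0):
        raise ValueError("instantaneous rate must stay positive")
    integral = np.concatenate([[0.0], np.cumsum(rate) * dt / 60.0])
    t_edges = np.concatenate([t, [t[-1] + dt]])
    n_beats = int(np.floor(integral[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    rpeaks = np.interp(targets, integral, t_edges)

    if physio.ectopic_rate > 0:
        n_ect = rng.poisson(physio.ectopic_rate * duration / 60.0)
        if n_ect:
            ect = rng.uniform(0.0, duration, size=n_ect)
            rpeaks = np.sort(np.concatenate([rpeaks, ect]))
    series = PhysioTimeSeries(rate, fs=1.0 / dt, t0=0.0, channel="hr_bpm")
    return rpeaks, series


def _qrs_template(t: np.ndarray) -> np.ndarray:
    """Simple QRS complex: dominant R wave with small Q/S deflections (mV)."""
    return (
        1.0 * np.exp(-(t**2) / (2 * 0.008**2))
        - 0.15 * np.exp(-((t + 0.025) ** 2) / (2 * 0.008**2))
        - 0.2 * np.exp(-((t - 0.025) ** 2) / (2 * 0.008**2))
    )


def synthesize_ecg(
    rpeak_times: np.ndarray,
    fs: float = 1024.0,
    duration: float | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> PhysioTimeSeries:
    """Place a template QRS complex at each R-peak time.

    Gives an end-to-end testbed for QRS detection; morphology beyond the
    QRS template (P/T waves) is deliberately omitted.
    """
    rng = np.random.default_rng(seed)
    rpeak_times = np.asarray(rpeak_times, dtype=float)
    if duration is None:
        duration = float(rpeak_times[-1]) + 1.0
    t = np.arange(0.0, duration, 1.0 / fs)
    ecg = np.zeros_like(t)
    half = int(round(0.06 * fs))
    for rp in rpeak_times:
        i = int(round(rp * fs))
        lo, hi = max(i - half, 0), min(i + half, len(t))
        ecg[lo:hi] += _qrs_template(t[lo:hi] - rp)
    if noise_sd > 0:
        ecg = ecg + noise_sd * rng.standard_normal(len(t))
    return PhysioTimeSeries(ecg, fs=fs, t0=0.0, channel="ecg_mv")
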