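"""Synthetic behavioural sessions from a two-stage SDT observer.

The generative observer turns a motion stimulus into a binary left/right
choice and a 0-100 confidence rating.  The decision variable is the signed
stimulus mean corrupted by the combination of internal noise and the
stimulus' own direction variability; choice compares the standardized
decision variable to a condition-specific criterion; confidence is a
monotone (logistic) map of the distance between decision variable and
criterion, degraded by optional type-2 noise and shifted by a per-condition
confidence bias.  Injecting known criterion and confidence-bias patterns
per cue x variance cell gives every behavioural analysis a ground truth to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .staircase import StaircaseConfig, StaircaseState, staircase_update

__all__ = [
    "ObserverParams",
    "simulate_observer_trial",
    "generate_behavior",
    "CUES",
    "VARIANCES",
    "CONDITIONS",
]

CUES = ("neutral", "disgust")
VARIANCES = ("low", "high")
#: condition labels in the conventional order NL, NH, DL, DH
CONDITIONS = tuple(f"{c[0].upper()}{v[0].upper()}" for c in CUES for v in VARIANCES)


def _as_2x2(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"{name} must be a 2x2 array (cue x variance)")
    return arr


@dataclass
class ObserverParams:
    """Generative parameters of the two-stage SDT observer.

    Attributes
    ----------
    sdt_sigma_internal : float
        SD of internal (neural) noise added to the perceived mean, degrees.
    n_eff_dots : float
        Effective number of independently sampled dots: the stimulus'
        external direction SD contributes ``sigma/sqrt(n_eff_dots)`` degrees
        of noise to the perceived mean, so high-variance stimuli are
        genuinely harder at matched means.
    criterion_c : float
        Baseline type-1 criterion in z units (0 = unbiased).
    conf_noise : float
        SD of Gaussian type-2 noise added to the confidence evidence
        (z units); 0 gives an ideal confidence observer (M-Ratio = 1).
    cue_variance_c_shift : 2x2 array
        Additive criterion offsets per (cue, variance) cell, z units,
        rows ordered (neutral, disgust) and columns (low, high).
    cue_variance_conf_shift : 2x2 array
        Additive confidence-bias offsets per cell on the 0-100 scale
        (negative = more conservative confidence reports).
    conf_scale : float
        Scale (z units) of the logistic confidence map; larger values
        spread ratings over more of the 0-100 range.
    rt_median, rt_sigma : float
        Log-normal RT parameters (seconds); condition effects enter through
        ``rt_variance_slowdown`` which multiplies the median on
        high-variance trials.
    rt_deadline : float
        Response window (s); trials with RT beyond it are flagged missed.
    sigma_levels : (float, float)
        Direction SDs of the (low, high) variance conditions, degrees.
    """

    sdt_sigma_internal: float = 1.0
    n_eff_dots: float = 25.0
    criterion_c: float = 0.0
    conf_noise: float = 0.25
    cue_variance_c_shift: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [0.15, -0.05]])
    )
    cue_variance_conf_shift: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, -5.0], [-2.5, -2.5]])
    )
    conf_scale: float = 1.5
    rt_median: float = 0.40
    rt_sigma: float = 0.35
    rt_variance_slowdown: float = 1.08
    rt_deadline: float = 0.8
    sigma_levels: tuple[float, float] = (15.0, 25.0)

    def __post_init__(self) -> None:
        if self.sdt_sigma_internal <= 0:
            raise ValueError("sdt_sigma_internal must be > 0")
        if self.conf_noise < 0:
            raise ValueError("conf_noise must be >= 0")
        self.cue_variance_c_shift = _as_2x2(self.cue_variance_c_shift, "cue_variance_c_shift")
        self.cue_variance_conf_shift = _as_2x2(
            self.cue_variance_conf_shift, "cue_variance_conf_shift"
        )

    def effective_sigma(self, stimulus_sigma: float) -> float:
        """Total decision-variable SD (degrees) for a given direction SD."""
        return float(
            np.hypot(self.sdt_sigma_internal, stimulus_sigma / np.sqrt(self.n_eff_dots))
        )

    def variance_label(self, stimulus_sigma: float) -> str:
        lo, hi = self.sigma_levels
        return "low" if abs(stimulus_sigma - lo) <= abs(stimulus_sigma - hi) else "high"

    def condition_shifts(self, cue: str, variance: str) -> tuple[float, float]:
        i, j = CUES.index(cue), VARIANCES.index(variance)
        return (
            float(self.cue_variance_c_shift[i, j]),
            float(self.cue_variance_conf_shift[i, j]),
        )


def _confidence_map(distance: np.ndarray | float, scale: float) -> np.ndarray | float:
    """Monotone map from criterion distance (z units) to [0, 100].

    A logistic squashed to pass through 0 at zero distance:
    ``100 * (2 / (1 + exp(-d/scale)) - 1)``.
    """
    return 100.0 * (2.0 / (1.0 + np.exp(-np.asarray(distance, float) / scale)) - 1.0)


def simulate_observer_trial(
    params: ObserverParams,
    stimulus,
    seed: int | np.random.Generator | None = None,
    cue: str = "neutral",
) -> tuple[str, bool, int, float]:
    """Simulate one trial: returns (choice, correct, confidence, rt).

    The decision variable is ``signed_mean + N(0, sigma_eff)`` standardized
    by ``sigma_eff``; choice is right iff it exceeds the condition criterion;
    confidence is the logistic map of |decision variable - criterion| plus
    type-2 noise and the condition confidence bias, rounded and clipped to
    the 0-100 integer scale.
    """
    rng = np.random.default_rng(seed)
    variance = params.variance_label(stimulus.sigma)
    c_shift, conf_shift = params.condition_shifts(cue, variance)
    sigma_eff = params.effective_sigma(stimulus.sigma)
    z = (stimulus.signed_mean + sigma_eff * rng.standard_normal()) / sigma_eff
    criterion = params.criterion_c + c_shift
    choice = "right" if z > criterion else "left"
    correct = choice == stimulus.side
    distance = abs(z - criterion) + params.conf_noise * rng.standard_normal()
    confidence = _confidence_map(max(distance, 0.0), params.conf_scale) + conf_shift
    confidence = int(np.clip(np.round(confidence), 0, 100))
    median = params.rt_median * (
        params.rt_variance_slowdown if variance == "high" else 1.0
    )
    rt = float(stats.lognorm.rvs(params.rt_sigma, scale=median, random_state=rng))
    return choice, correct, confidence, rt


def _balanced_blocks(n_trials: int, n_blocks: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Condition sequence: each block holds equal counts of the four cells,
    randomly interleaved."""
    per_block = n_trials // n_blocks
    if per_block % 4:
        raise ValueError("trials per block must be divisible by 4")
    cells = [(c, v) for c in CUES for v in VARIANCES]
    seq: list[tuple[str, str]] = []
    for _ in range(n_blocks):
        block = cells * (per_block // 4)
        rng.shuffle(block)
        seq.extend(block)
    return seq


def generate_behavior(
    n_trials: int = 640,
    observer: ObserverParams | None = None,
    staircase: StaircaseConfig | None = None,
    n_blocks: int = 10,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one subject's behavioural session as a trial table.

    Low-variance trials take their signal mean from an adaptive
    2-correct-down/1-wrong-up staircase (one independent staircase per cue
    condition); high-variance trials are yoked to the most recent
    low-variance trial of the same cue and never feed the staircase.
    Conditions are balanced (n_trials/4 each) and randomly interleaved
    within blocks.

    Returns a DataFrame with TrialRecord columns: trial_index, block, cue,
    variance, side, signal_mean, choice, correct, confidence, rt, missed.
    """
    if n_trials % 4:
        raise ValueError("n_trials must be divisible by 4 for condition balance")
    if n_trials % n_blocks:
        raise ValueError("n_trials must be divisible by n_blocks")
    observer = observer or ObserverParams()
    staircase = staircase or StaircaseConfig()
    rng = np.random.default_rng(seed)
    sequence = _balanced_blocks(n_trials, n_blocks, rng)
    per_block = n_trials // n_blocks
    sigma_of = dict(zip(VARIANCES, observer.sigma_levels))

    staircases = {cue: StaircaseState.create(staircase) for cue in CUES}
    last_low_mean: dict[str, float] = {}  # most recent low-variance signal mean per cue
    rows = []
    from .staircase import MotionStimulusSpec  # local to avoid clutter above

    for idx, (cue, variance) in enumerate(sequence):
        if variance == "low":
            mean = staircases[cue].level
            last_low_mean[cue] = float(mean)
        else:
            mean = last_low_mean.get(cue, staircase.initial)
        side = "right" if rng.random() < 0.5 else "left"
        spec = MotionStimulusSpec(
            side=side, mean_orientation=float(mean), sigma=sigma_of[variance]
        )
        choice, correct, confidence, rt = simulate_observer_trial(
            observer, spec, seed=rng, cue=cue
        )
        missed = rt > observer.rt_deadline
        if variance == "low":
            staircases[cue] = staircase_update(staircases[cue], correct)
        rows.append(
            dict(
                trial_index=idx,
                block=idx // per_block,
                cue=cue,
                variance=variance,
                side=side,
                signal_mean=float(mean),
                choice=choice,
                correct=bool(correct),
                confidence=int(confidence),
                rt=float(rt),
                missed=bool(missed),
            )
        )
    return pd.DataFrame(rows)
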