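"""Global-motion stimulus statistics and the adaptive performance staircase.

The discrimination task presents a field of coherently drifting dots whose
per-dot directions are drawn from a Gaussian centred slightly left or right
of vertical.  Task difficulty is the unsigned mean offset; sensory noise is
the direction SD (15 deg or 25 deg in the 2x2 design).  A two-correct-down /
one-wrong-up (Levitt) staircase adjusts the mean offset of *low-variance*
trials so that accuracy converges on ~70.7% correct; high-variance trials
reuse (are "yoked" to) the mean of the previous low-variance trial of the
same cue condition so that mean and variance stay orthogonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MotionStimulusSpec",
    "StaircaseConfig",
    "StaircaseState",
    "sample_dot_directions",
    "staircase_update",
    "run_staircase_session",
    "yoke_high_variance_mean",
]


@dataclass(frozen=True)
class MotionStimulusSpec:
    """Statistical description of one random-dot motion stimulus.

    Parameters
    ----------
    side : {"left", "right"}
        Sign of the mean direction relative to vertical (left = negative).
    mean_orientation : float
        Unsigned mean offset from vertical, degrees, >= 0.
    sigma : float
        SD of per-dot directions, degrees (15 or 25 in the standard design).
    n_dots : int
        Number of dots (default 1000).
    """

    side: str
    mean_orientation: float
    sigma: float
    n_dots: int = 1000

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.mean_orientation < 0:
            raise ValueError("mean_orientation must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")

    @property
    def signed_mean(self) -> float:
        """Mean direction in degrees, negative for leftward stimuli."""
        return self.mean_orientation if self.side == "right" else -self.mean_orientation


def sample_dot_directions(
    spec: MotionStimulusSpec, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw per-dot directions for one stimulus.

    Each direction is ``signed mean + N(0, sigma)`` in degrees.  Directions
    are plain real-valued angles: for the small means (< ~10 deg) and SDs
    (<= 25 deg) of the design the probability of a draw beyond +/-180 deg is
    negligible, so no circular wrapping is applied.
    """
    if spec.sigma < 0 or spec.n_dots < 1:
        raise ValueError("sigma must be >= 0 and n_dots >= 1")
    rng = np.random.default_rng(seed)
    return spec.signed_mean + spec.sigma * rng.standard_normal(spec.n_dots)


@dataclass(frozen=True)
class StaircaseConfig:
    """Tunables of the adaptive staircase.

    initial : starting mean orientation, degrees.
    step : additive step size, degrees.
    step_min : floor for the step size when halving is enabled.
    halving : halve the step at each direction reversal (down to step_min).
    level_min, level_max : clipping bounds for the level, degrees.
    """

    initial: float = 8.0
    step: float = 0.5
    step_min: float = 0.1
    halving: bool = False
    level_min: float = 0.1
    level_max: float = 45.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.step_min <= 0:
            raise ValueError("step and step_min must be > 0")
        if not (self.level_min < self.level_max):
            raise ValueError("level_min must be < level_max")


@dataclass(frozen=True)
class StaircaseState:
    """Current state of one 2-correct-down / 1-wrong-up staircase."""

    level: float
    step: float
    n_correct_in_row: int = 0
    n_reversals: int = 0
    last_direction: int = 0  # -1 down, +1 up, 0 none yet
    config: StaircaseConfig = field(default_factory=StaircaseConfig)
    history: tuple = ()

    @classmethod
    def create(cls, config: StaircaseConfig | None = None) -> "StaircaseState":
        config = config or StaircaseConfig()
        return cls(level=config.initial, step=config.step, config=config)


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one low-variance trial outcome.

    Two consecutive correct responses make the task harder (level - step);
    any error makes it easier (level + step).  This is Levitt's 2-down-1-up
    rule in difficulty space, whose equilibrium is P(correct) = sqrt(0.5)
    ~= 70.7%.  Reversals (direction changes) optionally halve the step.
    """
    cfg = state.config
    history = state.history + ((state.level, bool(correct)),)
    if correct and state.n_correct_in_row == 0:
        # first correct of a potential pair: level unchanged
        return replace(state, n_correct_in_row=1, history=history)

    direction = -1 if correct else +1  # -1: harder (down), +1: easier (up)
    step = state.step
    n_reversals = state.n_reversals
    if state.last_direction != 0 and direction != state.last_direction:
        n_reversals += 1
        if cfg.halving:
            step = max(step / 2.0, cfg.step_min)
    level = float(np.clip(state.level + direction * step, cfg.level_min, cfg.level_max))
    return replace(
        state,
        level=level,
        step=step,
        n_correct_in_row=0,
        n_reversals=n_reversals,
        last_direction=direction,
        history=history,
    )


def run_staircase_session(
    observer: Callable[[float], float],
    n_trials: int,
    config: StaircaseConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[tuple[float, bool]], float]:
    """Run a simulated staircase session against a psychometric observer.

    Parameters
    ----------
    observer : callable
        Maps a level (degrees) to P(correct), in [0, 1], monotone
        non-decreasing in level (non-increasing in difficulty).
    n_trials : int
        Number of trials (>= 10).
    config, seed :
        Staircase configuration and RNG seed.

    Returns
    -------
    history : list of (level, correct)
    converged_accuracy : float
        Mean accuracy over the second half of the session.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10")
    rng = np.random.default_rng(seed)
    state = StaircaseState.create(config)
    outcomes: list[tuple[float, bool]] = []
    for _ in range(n_trials):
        p = float(observer(state.level))
        if not 0.0 <= p <= 1.0:
            raise ValueError("observer must return probabilities in [0, 1]")
        correct = bool(rng.random() < p)
        outcomes.append((state.level, correct))
        state = staircase_update(state, correct)
    second_half = outcomes[n_trials // 2 :]
    accuracy = float(np.mean([c for _, c in second_half]))
    return outcomes, accuracy


def yoke_high_variance_mean(
    trial_history: Sequence[tuple[str, str, float]],
    cue: str,
    initial_level: float = 8.0,
) -> float:
    """Mean orientation for a high-variance trial, yoked to the staircase.

    ``trial_history`` holds (variance, cue, signal_mean) triples of completed
    trials.  Returns the signal mean of the most recent *low*-variance trial
    with the same cue; before any such trial exists, falls back to the
    staircase's initial level (logged).  High-variance outcomes never feed
    back into the staircase, which keeps signal mean and variance orthogonal.
    """
    for variance, trial_cue, signal_mean in reversed(trial_history):
        if variance == "low" and trial_cue == cue:
            return float(signal_mean)
    logger.warning(
        "no prior low-variance %s trial; yoking to initial level %.3g", cue, initial_level
    )
    warnings.warn(
        f"no prior low-variance {cue} trial; using initial level", stacklevel=2
    )
    return float(initial_level)
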