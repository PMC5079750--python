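import numpy as np
import pandas as pd
import pytest

from metaphysio import ObserverParams, generate_behavior


@pytest.fixture(scope="session")
def session_trials() -> pd.DataFrame:
    """One deterministic 320-trial behavioural session shared across tests."""
    return generate_behavior(n_trials=320, n_blocks=5, seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def ideal_observer_counts(
    n: int, d_prime: float, criterion: float = 0.0, seed: int = 0,
    conf_noise: float = 0.0,
):
    """Confidence counts from an SDT observer whose confidence is a monotone
    map of the decision variable (quartile-binned)."""
    from metaphysio import confidence_counts
    from metaphysio.behavior import bin_confidence_quartiles

    rng = np.random.default_rng(seed)
    side = rng.random(n) < 0.5
    x = np.where(side, d_prime / 2.0, -d_prime / 2.0) + rng.standard_normal(n)
    choice = x > criterion
    evidence = np.abs(x - criterion) + conf_noise * rng.standard_normal(n)
    conf = np.clip(100.0 * (2.0 / (1.0 + np.exp(-np.maximum(evidence, 0) / 1.5)) - 1.0), 0, 100)
    bins = bin_confidence_quartiles(conf)
    return confidence_counts(
        np.where(side, "right", "left"), np.where(choice, "right", "left"), bins
    )
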