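import numpy as np
import pytest

from tteval import SurvivalData, simulate_model_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def exp_pool():
    """A large all-event pool with constant hazard 0.08/month."""
    return simulate_model_pool(
        100_000, rate=0.08, rng=np.random.default_rng(424242)
    )


def random_survival_data(rng, n_max=30, censor_p=0.3, scale=10.0):
    """Small random right-censored dataset with at least one event."""
    n = int(rng.integers(3, n_max + 1))
    times = rng.exponential(scale, n).round(3)
    events = rng.random(n) > censor_p
    if not events.any():
        events[int(rng.integers(0, n))] = True
    return SurvivalData(times, events)
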