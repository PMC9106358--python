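import numpy as np
import pytest

from addictomir import AgentParams


@pytest.fixture
def steady_agent() -> AgentParams:
    """A moderately active agent used across schedule tests."""
    return AgentParams(active_rate=12.0, inactive_rate=2.0,
                       persistence_bias=0.6, motivation_cap=100.0,
                       punishment_sensitivity=0.85)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def brute_force_shock_counts(press_times, reset_s=60.0, timeout_s=10.0,
                             duration_s=3000.0):
    """Independent replay of the shock-test rules, written from the schedule
    description: 4th active response of a cycle -> shock only; 5th -> shock +
    pellet (then a 10-s time-out); cycle resets if the 5th response does not
    follow the 4th within one minute (that shock stands)."""
    shocks = pellets = 0
    cycle = 0
    t4 = None
    timeout_until = -1.0
    for t in press_times:
        if t > duration_s:
            break
        if t < timeout_until:
            continue
        if cycle == 4 and t - t4 > reset_s:
            cycle = 0
            t4 = None
        cycle += 1
        if cycle == 4:
            shocks += 1
            t4 = t
        elif cycle == 5:
            shocks += 1
            pellets += 1
            cycle = 0
            t4 = None
            timeout_until = t + timeout_s
    return shocks, pellets
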