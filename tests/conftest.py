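import numpy as np
import pytest

from reachfit import (
    MarkerTrajectory,
    default_profiles,
    minimum_jerk,
    simulate_trial,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def adult_trial(profiles):
    """One noisy adult trial in the 180-degree condition."""
    return simulate_trial(profiles["adult"], "180", seed=1)


@pytest.fixture(scope="session")
def child6_trial(profiles):
    return simulate_trial(profiles["child6"], "180", seed=1)


def make_trajectory(positions, rate_hz=120.0, label="wrist", valid=None):
    positions = np.asarray(positions, dtype=float)
    if valid is None:
        valid = np.ones(len(positions), dtype=bool)
    return MarkerTrajectory(label=label, positions=positions,
                            valid=np.asarray(valid, bool), rate_hz=rate_hz)


def min_jerk_positions(amplitude_mm, duration_s, rate_hz=120.0,
                       direction=(1.0, 0.0, 0.0), pad_s=0.2):
    """Straight minimum-jerk reach with stationary padding on both sides."""
    n_pad = int(pad_s * rate_hz)
    n_move = int(round(duration_s * rate_hz))
    tau = np.arange(n_move + 1) / n_move
    s = minimum_jerk(tau)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    path = amplitude_mm * np.outer(s, d)
    pos = np.vstack([
        np.repeat(path[:1], n_pad, axis=0),
        path,
        np.repeat(path[-1:], n_pad, axis=0),
    ])
    return pos


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
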