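import numpy as np
import pytest

from forageworld import envgen, session


@pytest.fixture(scope="session")
def smooth_env():
    return envgen.sample_smooth_environment(seed=1)


@pytest.fixture(scope="session")
def random_env():
    return envgen.sample_random_environment(seed=7)


@pytest.fixture(scope="session")
def walk_session(smooth_env):
    """Short group random-walk session shared across tests."""
    return session.generate_session("random_walk", smooth_env, {"duration": 40.0}, seed=3)


def make_pull_fixture(env, duration_scale=1.0):
    """Two-player script engineered to contain exactly one pull event.

    Player 1 (leader) departs from player 0, then stops; player 0 (follower)
    then approaches. Distances: 3 -> 27 -> 3; strength 0.64, disparity 1.0,
    duration 11 s (scaled by ``duration_scale``).
    """
    s = duration_scale
    waypoints = {
        0: [(0.0, 0.0, 0.0), (6.0 * s, 0.0, 0.0), (11.0 * s, 27.0, 0.0), (12.0 * s, 27.0, 0.0)],
        1: [(0.0, 3.0, 0.0), (1.0 * s, 3.0, 0.0), (5.0 * s, 30.0, 0.0), (12.0 * s, 30.0, 0.0)],
    }
    return session.generate_session(
        "scripted", env, {"waypoints": waypoints, "duration": 12.0 * s}, seed=0
    )
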