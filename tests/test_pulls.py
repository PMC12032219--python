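import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forageworld import pulls, session

from conftest import make_pull_fixture


def test_strength_hand_values():
    assert pulls.pull_strength(10, 20, 5) == pytest.approx(0.2)
    assert pulls.pull_strength(10, 10, 5) == pytest.approx(0.0)
    for c in (0.1, 2.0, 37.0):
        assert pulls.pull_strength(10 * c, 20 * c, 5 * c) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        pulls.pull_strength(0, 0, 0)


@settings(derandomize=True, max_examples=50)
@given(
    d1=st.floats(0.1, 100),
    d2=st.floats(0.1, 100),
    d3=st.floats(0.1, 100),
    c=st.floats(0.01, 50),
)
def test_strength_properties(d1, d2, d3, c):
    """Strength is scale-invariant, bounded in [0, 1], and symmetric under
    reversing the excursion."""
    s = pulls.pull_strength(d1, d2, d3)
    assert 0.0 <= s <= 1.0
    assert pulls.pull_strength(c * d1, c * d2, c * d3) == pytest.approx(s, rel=1e-9)
    assert pulls.pull_strength(d3, d2, d1) == pytest.approx(s, rel=1e-9)


def test_disparity_hand_values():
    assert pulls.pull_disparity((2.0, 2.0), (2.0, 2.0)) == pytest.approx(0.0)
    assert pulls.pull_disparity((5.0, 0.0), (0.0, 5.0)) == pytest.approx(1.0)
    assert pulls.pull_disparity((3.0, 1.0), (1.0, 3.0)) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        pulls.pull_disparity((0.0, 1.0), (0.0, 1.0))


def test_minmaxmin_monotone_none():
    assert pulls.minmaxmin_candidates(np.linspace(0, 30, 100)) == []
    assert pulls.minmaxmin_candidates(np.linspace(30, 0, 100)) == []


def test_minmaxmin_single_excursion():
    d = np.concatenate([np.linspace(10, 20, 50), np.linspace(20, 5, 60)[1:]])
    cands = pulls.minmaxmin_candidates(d)
    assert len(cands) == 1
    i1, i2, i3 = cands[0]
    assert (i1, i2, i3) == (0, 49, len(d) - 1)


def test_minmaxmin_subthreshold_jitter_merged():
    d = np.concatenate([np.linspace(10, 20, 50), np.linspace(20, 5, 60)[1:]])
    rng = np.random.default_rng(0)
    noisy = d + rng.uniform(-0.4, 0.4, len(d))
    cands = pulls.minmaxmin_candidates(noisy)
    assert len(cands) == 1
    i1, i2, i3 = cands[0]
    assert abs(i2 - 49) <= 3 and i1 <= 2 and i3 >= len(d) - 3


def test_minmaxmin_plateau_first_index():
    d = np.array([10.0, 10.0, 20.0, 20.0, 20.0, 5.0, 5.0])
    (i1, i2, i3), = pulls.minmaxmin_candidates(d)
    assert i2 == 2  # first index of the max plateau


def test_scripted_fixture_yields_exactly_one_pull(smooth_env):
    fixture = make_pull_fixture(smooth_env)
    events = pulls.detect_pulls(fixture)
    assert len(events) == 1
    e = events[0]
    assert e.leader == 1 and e.follower == 0
    assert e.strength > 0.1 and e.disparity > 0.1 and e.duration >= 3.0
    # hand-computed from the script: d goes 3 -> 30 -> 3
    assert e.strength == pytest.approx((27 * 27) / (33 * 33), abs=0.02)
    assert e.disparity == pytest.approx(1.0, abs=0.02)


def test_compressed_fixture_fails_duration_filter(smooth_env):
    fixture = make_pull_fixture(smooth_env, duration_scale=2.5 / 12.0)  # total 2.5 s
    assert pulls.detect_pulls(fixture) == []


def test_symmetric_approach_fails_disparity(smooth_env):
    waypoints = {
        0: [(0.0, 15.0, 0.0), (4.0, 0.0, 0.0), (8.0, 15.0, 0.0)],
        1: [(0.0, 18.0, 0.0), (4.0, 33.0, 0.0), (8.0, 18.0, 0.0)],
    }
    s = session.generate_session("scripted", smooth_env, {"waypoints": waypoints, "duration": 8.0}, 0)
    assert pulls.detect_pulls(s) == []


def test_relabeling_swaps_roles(smooth_env):
    fixture = make_pull_fixture(smooth_env)
    swapped = session.SessionLogs(
        fixture.player_log.assign(player=1 - fixture.player_log["player"]),
        fixture.map_log,
        fixture.visibility_log,
        fixture.environment,
        fixture.meta,
    )
    (a,) = pulls.detect_pulls(fixture)
    (b,) = pulls.detect_pulls(swapped)
    assert (b.leader, b.follower) == (1 - a.leader, 1 - a.follower)
    assert b.strength == pytest.approx(a.strength) and b.disparity == pytest.approx(a.disparity)


def test_rigid_motion_invariance(smooth_env):
    fixture = make_pull_fixture(smooth_env)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    plog = fixture.player_log.copy()
    xy = plog[["x", "z"]].to_numpy() @ R.T + np.array([5.0, -11.0])
    plog["x"], plog["z"] = xy[:, 0], xy[:, 1]
    moved = session.SessionLogs(plog, fixture.map_log, fixture.visibility_log,
                                fixture.environment, fixture.meta)
    (a,) = pulls.detect_pulls(fixture)
    (b,) = pulls.detect_pulls(moved)
    assert b.t1 == a.t1 and b.t3 == a.t3
    assert b.strength == pytest.approx(a.strength, abs=1e-9)
    assert b.disparity == pytest.approx(a.disparity, abs=1e-9)


def test_threshold_relaxation_monotone(walk_session):
    counts = [
        len(pulls.detect_pulls(walk_session, disparity_min=d)) for d in (0.4, 0.2, 0.1, 0.0)
    ]
    assert all(a <= b for a, b in zip(counts, counts[1:]))
    s_counts = [
        len(pulls.detect_pulls(walk_session, strength_min=s)) for s in (0.4, 0.2, 0.1, 0.0)
    ]
    assert all(a <= b for a, b in zip(s_counts, s_counts[1:]))


def test_frame_and_leadership_index(smooth_env):
    fixture = make_pull_fixture(smooth_env)
    events = pulls.detect_pulls(fixture)
    df = pulls.pulls_to_frame(events)
    assert list(df.columns)[:5] == ["player_i", "player_j", "t1", "t2", "t3"]
    idx = pulls.leadership_index(events)
    assert idx[1] == 1 and idx[0] == -1
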