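"""Leader-follower "pull" event detection from dyadic distance series.

A pull is a min-max-min excursion in the distance between two players: the
pair first separates (one player departs) and then re-converges (the other
follows). Candidate triples (t1, t2, t3) are alternating extrema of the 20 Hz
dyadic distance series, with sub-threshold wiggles (default 1 block) merged
away. Candidates are kept as pulls only if they pass four filters:

* strength  S = |d2-d1| |d3-d2| / ((d1+d2)(d2+d3)) > 0.1  -- the change in
  distance is meaningful relative to the absolute distance (scale-invariant);
* disparity delta > 0.1 -- the movement is asymmetric between the partners;
* leadership -- the player who moved more in [t1, t2] (the leader) differs
  from the player who moved more in [t2, t3] (the follower);
* duration t3 - t1 >= 3 s (a block takes 2.25 s to destroy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NOISE_THRESHOLD = 1.0  # blocks
STRENGTH_MIN = 0.1
DISPARITY_MIN = 0.1
DURATION_MIN = 3.0  # seconds


@dataclass(frozen=True)
class PullEvent:
    """One dyadic min-max-min episode passing all filters."""

    dyad: tuple[int, int]
    t1: float
    t2: float
    t3: float
    strength: float
    disparity: float
    leader: int
    follower: int

    @property
    def duration(self) -> float:
        return self.t3 - self.t1


def pull_strength(d1: float, d2: float, d3: float) -> float:
    """Absolute change in dyadic distance relative to absolute distance.

    Homogeneous of degree zero: scaling all three distances leaves it unchanged.
    """
    denom = (d1 + d2) * (d2 + d3)
    if denom <= 0:
        raise ValueError("strength undefined: zero denominator")
    return abs(d2 - d1) * abs(d3 - d2) / denom


def pull_disparity(dx_i: tuple[float, float], dx_j: tuple[float, float]) -> float:
    """Extent to which one partner moves more than the other in each segment.

    ``dx_i``/``dx_j`` are the (first segment, second segment) displacements of
    the two players. 0 when both always move equally; 1 when each segment is
    driven entirely by one (different) player.
    """
    s1 = dx_i[0] + dx_j[0]
    s2 = dx_i[1] + dx_j[1]
    if s1 <= 0 or s2 <= 0:
        raise ValueError("disparity undefined: zero total movement in a segment")
    return abs(dx_i[0] - dx_j[0]) * abs(dx_i[1] - dx_j[1]) / (s1 * s2)


def minmaxmin_candidates(
    distance: np.ndarray,
    noise_threshold: float = NOISE_THRESHOLD,
) -> list[tuple[int, int, int]]:
    """Candidate (t1, t2, t3) index triples from alternating extrema.

    Extrema are committed only when the series subsequently moves against the
    current direction by more than ``noise_threshold``, so sub-threshold
    jitter is merged; plateaus take the first index. Consecutive candidates
    share endpoints (a min closes one excursion and opens the next).
    """
    d = np.asarray(distance, dtype=float)
    if len(d) < 3:
        return []
    extrema: list[tuple[int, str]] = []
    # direction unknown at start: track running min and max until the range exceeds threshold
    i_min = i_max = 0
    direction = 0
    cur = (0, d[0])  # extremum in current direction
    pending = (0, d[0])  # best opposite-direction point since cur
    for i in range(1, len(d)):
        v = d[i]
        if direction == 0:
            if v < d[i_min]:
                i_min = i
            if v > d[i_max]:
                i_max = i
            if d[i_max] - d[i_min] > noise_threshold:
                if i_min < i_max:
                    extrema.append((i_min, "min"))
                    direction, cur = 1, (i_max, d[i_max])
                else:
                    extrema.append((i_max, "max"))
                    direction, cur = -1, (i_min, d[i_min])
                pending = (i, v)
            continue
        if direction == 1:
            if v > cur[1]:
                cur = (i, v)
                pending = (i, v)
            elif v < pending[1]:
                pending = (i, v)
            if cur[1] - pending[1] > noise_threshold:
                extrema.append((cur[0], "max"))
                direction, cur, pending = -1, pending, (i, v)
        else:
            if v < cur[1]:
                cur = (i, v)
                pending = (i, v)
            elif v > pending[1]:
                pending = (i, v)
            if pending[1] - cur[1] > noise_threshold:
                extrema.append((cur[0], "min"))
                direction, cur, pending = 1, pending, (i, v)
    extrema.append((cur[0], "max" if direction == 1 else "min"))

    triples = []
    for a in range(len(extrema) - 2):
        (i1, k1), (i2, k2), (i3, k3) = extrema[a : a + 3]
        if (k1, k2, k3) == ("min", "max", "min"):
            triples.append((i1, i2, i3))
    return triples


def detect_pulls(
    session,
    strength_min: float = STRENGTH_MIN,
    disparity_min: float = DISPARITY_MIN,
    duration_min: float = DURATION_MIN,
    noise_threshold: float = NOISE_THRESHOLD,
) -> list[PullEvent]:
    """All pull events in a session, every dyad evaluated independently.

    Applicable to group sessions and solo superposition baselines alike.
    Candidates whose disparity is undefined (a segment with zero total
    movement) cannot be asymmetric pulls and are dropped.
    """
    times, pos, _ = session.positions_wide()
    players = session.players
    events: list[PullEvent] = []
    for a in range(len(players)):
        for b in range(a + 1, len(players)):
            dist = np.linalg.norm(pos[:, a, :] - pos[:, b, :], axis=1)
            for i1, i2, i3 in minmaxmin_candidates(dist, noise_threshold):
                if times[i3] - times[i1] < duration_min:
                    continue
                strength = pull_strength(dist[i1], dist[i2], dist[i3])
                if strength <= strength_min:
                    continue
                dx_a = (
                    float(np.linalg.norm(pos[i2, a] - pos[i1, a])),
                    float(np.linalg.norm(pos[i3, a] - pos[i2, a])),
                )
                dx_b = (
                    float(np.linalg.norm(pos[i2, b] - pos[i1, b])),
                    float(np.linalg.norm(pos[i3, b] - pos[i2, b])),
                )
                try:
                    disparity = pull_disparity(dx_a, dx_b)
                except ValueError:
                    continue
                if disparity <= disparity_min:
                    continue
                leader = players[a] if dx_a[0] > dx_b[0] else players[b]
                follower = players[a] if dx_a[1] > dx_b[1] else players[b]
                if leader == follower:
                    continue
                events.append(
                    PullEvent(
                        dyad=(players[a], players[b]),
                        t1=float(times[i1]),
                        t2=float(times[i2]),
                        t3=float(times[i3]),
                        strength=float(strength),
                        disparity=float(disparity),
                        leader=leader,
                        follower=follower,
                    )
                )
    return events


def pulls_to_frame(events: list[PullEvent]) -> pd.DataFrame:
    """Tidy CSV-ready table of pull events."""
    return pd.DataFrame(
        [
            {
                "player_i": e.dyad[0],
                "player_j": e.dyad[1],
                "t1": e.t1,
                "t2": e.t2,
                "t3": e.t3,
                "strength": e.strength,
                "disparity": e.disparity,
                "leader": e.leader,
                "follower": e.follower,
                "duration": e.duration,
            }
            for e in events
        ]
    )


def leadership_index(events: list[PullEvent]) -> dict[int, int]:
    """n_leader - n_follower per player."""
    idx: dict[int, int] = {}
    for e in events:
        idx[e.leader] = idx.get(e.leader, 0) + 1
        idx[e.follower] = idx.get(e.follower, 0) - 1
    return idx
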