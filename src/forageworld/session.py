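"""Synthetic session logs in the experiment's format.

A session is one 120-s foraging round recorded at the game engine's native
20 Hz tick rate, split into three tidy logs:

* ``player_log`` -- per tick per player: time, XZ position, horizontal heading;
* ``map_log``    -- per block destruction: time, player, block, position, reward;
* ``visibility_log`` -- per tick per observer: which peers are inside the
  geometric field of view, and which reward splashes are visible.

Three generators provide sessions with known structure: ``agentsim`` renders
agent-based simulation episodes into logs, ``random_walk`` produces null
trajectories with no reward dependence (for false-positive calibration of the
temporal analyses), and ``scripted`` replays hand-written waypoint scripts
(e.g., pull-event fixtures). Solo rounds place four players on independent
replicate fields; :func:`solo_superposition` merges them as if they shared one
field, with shared block removal and one splash per reward event, providing
the asocial baseline used throughout the analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from forageworld import features as feat
from forageworld.envgen import EnvironmentGrid, load_environment

TICK = 0.05  # seconds; 20 Hz
DEFAULT_DURATION = 120.0
DESTRUCTION_TIME = 2.25  # seconds to destroy a block
DEFAULT_SPLASH_DURATION = 1.0  # seconds a splash stays observable

PLAYER_LOG_COLUMNS = ["time", "player", "x", "z", "hx", "hz"]
MAP_LOG_COLUMNS = ["time", "player", "block", "row", "col", "x", "z", "reward"]
VISIBILITY_LOG_COLUMNS = ["time", "observer", "kind", "target", "x", "z"]


class SchemaError(ValueError):
    """A log file or frame does not match the expected schema."""


class SessionValidationError(ValueError):
    """A session violates the invariants downstream analyses assume."""


@dataclass
class SessionLogs:
    """One round of player, map, and visibility logs plus metadata."""

    player_log: pd.DataFrame
    map_log: pd.DataFrame
    visibility_log: pd.DataFrame
    environment: EnvironmentGrid
    meta: dict = field(default_factory=dict)

    @property
    def players(self) -> list[int]:
        return sorted(int(p) for p in self.player_log["player"].unique())

    @property
    def duration(self) -> float:
        return float(self.meta.get("duration", DEFAULT_DURATION))

    def destroyed_before(self, t: float, player: int | None = None) -> set[int]:
        """Blocks destroyed at time <= t; restricted to one player's own field if given."""
        m = self.map_log[self.map_log["time"] <= t]
        if player is not None:
            m = m[m["player"] == player]
        return set(int(b) for b in m["block"])

    # features.assemble_choice_features queries the destroyed set through this name
    def available_mask_times(self, t: float, player: int | None = None) -> set[int]:
        return self.destroyed_before(t, player)

    def positions_wide(self):
        """(times, positions (T,P,2), headings (T,P,2)) in player order."""
        players = self.players
        piv = self.player_log.pivot_table(index="time", columns="player")
        times = piv.index.to_numpy()
        pos = np.stack([piv["x"][p].to_numpy() for p in players], axis=1)
        pos = np.stack([pos, np.stack([piv["z"][p].to_numpy() for p in players], axis=1)], axis=2)
        hd = np.stack(
            [
                np.stack([piv["hx"][p].to_numpy() for p in players], axis=1),
                np.stack([piv["hz"][p].to_numpy() for p in players], axis=1),
            ],
            axis=2,
        )
        return times, pos, hd


def _heading_from_velocity(dxz: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Unit headings from per-tick displacement; stationary ticks keep the last heading."""
    n = len(dxz)
    out = np.zeros((n, 2))
    cur = np.asarray(fallback, dtype=float)
    cur = cur / np.linalg.norm(cur)
    for i in range(n):
        norm = np.linalg.norm(dxz[i])
        if norm > 1e-12:
            cur = dxz[i] / norm
        out[i] = cur
    return out


def derive_visibility(
    player_log: pd.DataFrame,
    map_log: pd.DataFrame,
    environment: EnvironmentGrid,
    fov_degrees: float = feat.FOV_DEGREES,
    splash_duration: float = DEFAULT_SPLASH_DURATION,
) -> pd.DataFrame:
    """Geometric visibility log: visible peers per tick plus visible splash events.

    Splashes (rewarded destructions) are observable from any position for
    ``splash_duration`` seconds if the block location falls inside the FOV.
    """
    players = sorted(int(p) for p in player_log["player"].unique())
    times = np.sort(player_log["time"].unique())
    pos = {p: player_log[player_log["player"] == p].sort_values("time") for p in players}
    P = {p: pos[p][["x", "z"]].to_numpy() for p in players}
    H = {p: pos[p][["hx", "hz"]].to_numpy() for p in players}
    rows = []
    for obs in players:
        for tgt in players:
            if obs == tgt:
                continue
            mask = _fov_series(P[obs], H[obs], P[tgt], fov_degrees)
            for i in np.nonzero(mask)[0]:
                rows.append((times[i], obs, "player", tgt, P[tgt][i, 0], P[tgt][i, 1]))
    splashes = map_log[map_log["reward"] == 1]
    for _, ev in splashes.iterrows():
        t0 = float(ev["time"])
        window = (times > t0) & (times <= t0 + splash_duration)
        target_xy = np.array([[ev["x"], ev["z"]]])
        for obs in players:
            if obs == int(ev["player"]):
                continue
            idx = np.nonzero(window)[0]
            if len(idx) == 0:
                continue
            mask = _fov_series(P[obs][idx], H[obs][idx], np.repeat(target_xy, len(idx), 0), fov_degrees)
            for i, ok in zip(idx, mask):
                if ok:
                    rows.append((times[i], obs, "splash", int(ev["player"]), ev["x"], ev["z"]))
    return pd.DataFrame(rows, columns=VISIBILITY_LOG_COLUMNS)


def _fov_series(P_obs: np.ndarray, H_obs: np.ndarray, P_tgt: np.ndarray, fov_degrees: float) -> np.ndarray:
    """Per-tick FOV test of a moving target from a moving observer (vectorized over time)."""
    diff = P_tgt - P_obs
    dist = np.linalg.norm(diff, axis=1)
    norms = np.linalg.norm(H_obs, axis=1)
    cos_half = np.cos(np.deg2rad(fov_degrees) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("tk,tk->t", diff, H_obs / norms[:, None]) / np.where(dist > 0, dist, np.inf)
    return (cosang >= cos_half - 1e-12) | (dist == 0.0)


def _map_log_from_events(events: list[tuple], environment: EnvironmentGrid) -> pd.DataFrame:
    rows = []
    for t, player, block, reward in events:
        r, c = environment.grid_coords[block]
        x, z = environment.world_coords[block]
        rows.append((round(t, 4), int(player), int(block), int(r), int(c), x, z, int(reward)))
    return pd.DataFrame(rows, columns=MAP_LOG_COLUMNS).sort_values("time").reset_index(drop=True)


def generate_session(
    mode: str,
    env: EnvironmentGrid,
    config: dict | None = None,
    seed: int = 0,
) -> SessionLogs:
    """Generate a synthetic session. Modes: ``agentsim``, ``random_walk``, ``scripted``."""
    config = dict(config or {})
    if mode == "random_walk":
        return _generate_random_walk(env, config, seed)
    if mode == "scripted":
        return _generate_scripted(env, config, seed)
    if mode == "agentsim":
        from forageworld import agentsim

        agent_type = config.get("agent_type", "asocial")
        horizon = int(config.get("horizon", 400))
        result = agentsim.run_episode(env, agent_type, horizon=horizon, seed=seed, record=True)
        return agentsim.episode_to_session(result, env, config)
    raise ValueError(f"unknown session mode: {mode!r}")


def _generate_random_walk(env: EnvironmentGrid, config: dict, seed: int) -> SessionLogs:
    """Momentum random walks with reward-independent trajectories and destructions."""
    rng = np.random.default_rng(seed)
    n_players = int(config.get("n_players", 4))
    duration = float(config.get("duration", DEFAULT_DURATION))
    condition = config.get("condition", "group")
    speed = float(config.get("speed", 3.0))  # blocks per second
    momentum = float(config.get("momentum", 0.9))
    n_ticks = int(round(duration / TICK))
    lo, hi = -3.0, float(env.world_coords.max() + 3.0)

    frames = []
    positions = {}
    for p in range(n_players):
        xy = np.zeros((n_ticks, 2))
        xy[0] = rng.uniform(0, hi - 3.0, 2)
        v = rng.normal(0, 1, 2)
        v = v / np.linalg.norm(v) * speed * TICK
        sigma = speed * TICK * np.sqrt(1 - momentum**2)
        for t in range(1, n_ticks):
            v = momentum * v + rng.normal(0, sigma, 2)
            xy[t] = np.clip(xy[t - 1] + v, lo, hi)
        d = np.diff(xy, axis=0, prepend=xy[:1])
        hd = _heading_from_velocity(d, rng.normal(0, 1, 2))
        positions[p] = xy
        frames.append(
            pd.DataFrame(
                {
                    "time": np.round(np.arange(n_ticks) * TICK, 4),
                    "player": p,
                    "x": xy[:, 0],
                    "z": xy[:, 1],
                    "hx": hd[:, 0],
                    "hz": hd[:, 1],
                }
            )
        )
    player_log = pd.concat(frames, ignore_index=True)

    # reward-independent destruction schedule: nearest available block at each event
    mean_gap = float(config.get("mean_extra_gap", 1.5))
    events = []
    own_destroyed: dict[int, set] = {p: set() for p in range(n_players)}
    shared_destroyed: set = set()
    schedule = []
    for p in range(n_players):
        t = DESTRUCTION_TIME + rng.exponential(mean_gap)
        while t < duration:
            schedule.append((t, p))
            t += DESTRUCTION_TIME + rng.exponential(mean_gap)
    for t, p in sorted(schedule):
        tick = min(int(t / TICK), n_ticks - 1)
        taken = own_destroyed[p] if condition == "solo" else shared_destroyed
        avail = np.array([b for b in range(len(env.world_coords)) if b not in taken])
        if len(avail) == 0:
            continue
        d = np.linalg.norm(env.world_coords[avail] - positions[p][tick], axis=1)
        block = int(avail[np.argmin(d)])
        taken.add(block)
        own_destroyed[p].add(block)
        events.append((round(tick * TICK, 4), p, block, int(env.reward_at(block))))
    map_log = _map_log_from_events(events, env)
    if condition == "solo":
        # replicate fields: players cannot see each other or each other's splashes
        vis = pd.DataFrame(columns=VISIBILITY_LOG_COLUMNS)
    else:
        vis = derive_visibility(
            player_log, map_log, env,
            fov_degrees=float(config.get("fov_degrees", feat.FOV_DEGREES)),
            splash_duration=float(config.get("splash_duration", DEFAULT_SPLASH_DURATION)),
        )
    meta = {
        "condition": condition,
        "env_type": env.env_type,
        "duration": duration,
        "dt": TICK,
        "seed": seed,
        "mode": "random_walk",
    }
    return SessionLogs(player_log, map_log, vis, env, meta)


def _generate_scripted(env: EnvironmentGrid, config: dict, seed: int) -> SessionLogs:
    """Replay hand-written waypoint scripts; used for constructing exact fixtures."""
    waypoints = config["waypoints"]  # {player: [(t, x, z), ...]}
    duration = float(config.get("duration", max(w[-1][0] for w in waypoints.values())))
    n_ticks = int(round(duration / TICK)) + 1
    times = np.round(np.arange(n_ticks) * TICK, 4)
    frames = []
    for p, wps in waypoints.items():
        wps = sorted(wps)
        wt = np.array([w[0] for w in wps], dtype=float)
        wx = np.array([w[1] for w in wps], dtype=float)
        wz = np.array([w[2] for w in wps], dtype=float)
        x = np.interp(times, wt, wx)
        z = np.interp(times, wt, wz)
        d = np.diff(np.stack([x, z], axis=1), axis=0, prepend=[[x[0], z[0]]])
        hd = _heading_from_velocity(d, config.get("initial_heading", (1.0, 0.0)))
        frames.append(
            pd.DataFrame({"time": times, "player": int(p), "x": x, "z": z, "hx": hd[:, 0], "hz": hd[:, 1]})
        )
    player_log = pd.concat(frames, ignore_index=True)
    events = [
        (round(t, 4), int(p), int(b), int(env.reward_at(int(b))))
        for (t, p, b) in config.get("destructions", [])
    ]
    map_log = _map_log_from_events(events, env)
    vis = derive_visibility(player_log, map_log, env)
    meta = {
        "condition": config.get("condition", "group"),
        "env_type": env.env_type,
        "duration": duration,
        "dt": TICK,
        "seed": seed,
        "mode": "scripted",
    }
    return SessionLogs(player_log, map_log, vis, env, meta)


def solo_superposition(solo: SessionLogs | list[SessionLogs]) -> SessionLogs:
    """Merge solo replicate fields as if the players had shared one field.

    Block availability becomes shared (a block is gone once *any* player has
    destroyed it), every reward event keeps its own splash, and visibility is
    recomputed geometrically on the union of trajectories.
    """
    if isinstance(solo, list):
        envs = {(s.environment.env_type, s.environment.seed) for s in solo}
        if len(envs) != 1:
            raise ValueError("solo replicate fields use mismatched environments")
        player_log = pd.concat([s.player_log for s in solo], ignore_index=True)
        map_log = pd.concat([s.map_log for s in solo], ignore_index=True)
        base = solo[0]
    else:
        if solo.meta.get("condition") != "solo":
            raise ValueError("superposition baseline requires a solo session")
        player_log, map_log, base = solo.player_log, solo.map_log, solo
    map_log = map_log.sort_values("time").reset_index(drop=True)
    vis = derive_visibility(player_log, map_log, base.environment)
    meta = dict(base.meta)
    meta["condition"] = "solo_superposition"
    return SessionLogs(player_log.copy(), map_log, vis, base.environment, meta)


def validate_session(session: SessionLogs) -> None:
    """Raise :class:`SessionValidationError` if downstream invariants are violated."""
    problems = []
    for p in session.players:
        t = session.player_log.loc[session.player_log["player"] == p, "time"].to_numpy()
        gaps = np.diff(np.sort(t))
        if len(gaps) and not np.allclose(gaps, TICK, atol=1e-6):
            problems.append(f"player {p}: tick spacing not uniformly {TICK}s")
        h = session.player_log.loc[session.player_log["player"] == p, ["hx", "hz"]].to_numpy()
        if np.any(np.abs(np.linalg.norm(h, axis=1) - 1.0) > 1e-5):
            problems.append(f"player {p}: non-unit heading vector")
        mt = np.sort(session.map_log.loc[session.map_log["player"] == p, "time"].to_numpy())
        if len(mt) > 1 and np.min(np.diff(mt)) < DESTRUCTION_TIME - 1e-9:
            problems.append(f"player {p}: destructions closer than {DESTRUCTION_TIME}s")
    condition = session.meta.get("condition", "group")
    key = ["block"] if condition == "group" else ["player", "block"]
    if session.map_log.duplicated(subset=key).any():
        problems.append("a block was destroyed more than once")
    if len(session.map_log) and session.map_log["time"].max() > session.duration + 1e-9:
        problems.append("map log event beyond round duration")
    if problems:
        raise SessionValidationError("; ".join(problems))


def write_session(session: SessionLogs, path: str | Path) -> None:
    """Lossless round-trip serialization: one CSV per log plus JSON meta."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.player_log.to_csv(path / "player_log.csv", index=False)
    session.map_log.to_csv(path / "map_log.csv", index=False)
    session.visibility_log.to_csv(path / "visibility_log.csv", index=False)
    (path / "meta.json").write_text(json.dumps(session.meta))
    session.environment.save(path / "environment.csv")


def _check_schema(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    bad = df[columns].drop(columns=["kind"], errors="ignore").isna().any(axis=1)
    if bad.any():
        raise SchemaError(f"{name}: missing values at rows {list(df.index[bad][:10])}")
    return df


def read_session(path: str | Path) -> SessionLogs:
    path = Path(path)
    player_log = _check_schema(pd.read_csv(path / "player_log.csv"), PLAYER_LOG_COLUMNS, "player_log")
    map_log = _check_schema(pd.read_csv(path / "map_log.csv"), MAP_LOG_COLUMNS, "map_log")
    vis = pd.read_csv(path / "visibility_log.csv")
    if len(vis) == 0:
        vis = pd.DataFrame(columns=VISIBILITY_LOG_COLUMNS)
    else:
        vis = _check_schema(vis, VISIBILITY_LOG_COLUMNS, "visibility_log")
    meta = json.loads((path / "meta.json").read_text())
    env = load_environment(path / "environment.csv")
    return SessionLogs(player_log, map_log, vis, env, meta)
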