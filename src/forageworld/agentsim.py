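"""Agent-based simulation of the collective foraging task.

The task is modeled as a discrete-time sequential game with partial
observability: four agents move in cardinal directions on the block field,
observe one another and reward-reveal events only inside a 108.5-degree field
of view, and destroy blocks for binary rewards. Each agent runs a high-level
controller cycling through three modes: ``SelectDest`` (sample a destination
block from a softmax over block features), ``NavTo`` (greedy cardinal steps
toward it), and ``forage`` (a 9-timestep destruction countdown, matching the
2.25-s destruction time at 0.25 s per timestep).

Three agent types differ only in their feature sets, with all weights fixed
at 1: *asocial* agents use locality, block visibility, and their own GP reward
prediction; *unbiased social* agents add inverse distance to the average
position of any partners observed since their last choice; *biased social*
agents instead use only partners observed acquiring a reward (a visible
splash) since their last choice. Success-biased social learning is expected to
beat asocial search in smooth environments but not in random ones, while
unbiased imitation performs poorly in both.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from forageworld import gpclass
from forageworld.envgen import EnvironmentGrid, sample_random_environment, sample_smooth_environment
from forageworld.features import (
    FOV_DEGREES,
    compute_locality,
    inverse_distance,
    standardize_columns,
    visible_mask,
)

TIMESTEP_SECONDS = 0.25
FORAGE_STEPS = 9
DEFAULT_HORIZON = 400
N_AGENTS = 4
AGENT_TYPES = ("asocial", "unbiased_social", "biased_social")

#: World units moved per timestep: one block, i.e. 4 blocks/s at 0.25 s per
#: step, approximating the task's 4.3 blocks/s maximum movement speed.
MOVE_STEP = 1.0

# cardinal moves in fixed tie-break order: N, E, S, W
_CARDINALS = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, -1.0], [-1.0, 0.0]])


@dataclass
class AgentState:
    """One agent's controller mode, pose, belief, and observation buffers."""

    agent_id: int
    agent_type: str
    pos: np.ndarray
    heading: np.ndarray
    mode: str = "SelectDest"  # SelectDest | NavTo | forage
    dest_block: int = -1
    forage_k: int = 0
    total_reward: int = 0
    belief: gpclass.GPBeliefState = field(
        default_factory=lambda: gpclass.GPBeliefState()
    )
    seen_partners: dict[int, np.ndarray] = field(default_factory=dict)
    seen_success: set[int] = field(default_factory=set)


@dataclass
class SimWorld:
    """Shared world state: environment, agent states, and destroyed-block set."""

    environment: EnvironmentGrid
    agents: list[AgentState]
    destroyed: set[int] = field(default_factory=set)
    timestep: int = 0
    events: list[tuple] = field(default_factory=list)  # (t, agent, block, reward)
    trace_pos: list[np.ndarray] = field(default_factory=list)
    trace_heading: list[np.ndarray] = field(default_factory=list)

    @property
    def available(self) -> np.ndarray:
        return np.array(
            [b for b in range(len(self.environment.world_coords)) if b not in self.destroyed],
            dtype=int,
        )


def init_world(env: EnvironmentGrid, agent_type: str, rng: np.random.Generator) -> SimWorld:
    if agent_type not in AGENT_TYPES:
        raise ValueError(f"unknown agent type {agent_type!r}")
    agents = []
    n_side = int(np.sqrt(len(env.world_coords)))
    for i in range(N_AGENTS):
        node = rng.integers(0, n_side, size=2)
        heading = rng.normal(0, 1, 2)
        heading /= np.linalg.norm(heading)
        agents.append(
            AgentState(
                agent_id=i,
                agent_type=agent_type,
                pos=node.astype(float) * env.spacing,
                heading=heading,
            )
        )
    return SimWorld(environment=env, agents=agents)


def _destination_features(agent: AgentState, world: SimWorld, available: np.ndarray) -> np.ndarray:
    """Standardized feature matrix over available blocks for one agent's choice."""
    cand_xy = world.environment.world_coords[available]
    cols = {
        "locality": compute_locality(agent.pos, cand_xy),
        "visibility": visible_mask(
            agent.pos[None, :], agent.heading[None, :], cand_xy, FOV_DEGREES
        )[0].astype(float),
        "reward_prediction": gpclass.predict_many(agent.belief, cand_xy),
    }
    if agent.agent_type == "unbiased_social":
        qual = sorted(agent.seen_partners)
    elif agent.agent_type == "biased_social":
        qual = sorted(p for p in agent.seen_partners if p in agent.seen_success)
    else:
        qual = []
    if agent.agent_type != "asocial":
        if qual:
            # average proximity (inverse distance) over qualifying partners
            cols["social_proximity"] = np.mean(
                [inverse_distance(cand_xy, agent.seen_partners[p]) for p in qual], axis=0
            )
        else:
            cols["social_proximity"] = np.zeros(len(available))
    cols = standardize_columns(cols)
    return np.column_stack(list(cols.values()))


def select_destination(agent: AgentState, world: SimWorld, rng: np.random.Generator) -> int:
    """Sample a destination block from P(x) ∝ exp(f(x) · w) with all weights 1."""
    available = world.available
    if len(available) == 0:
        raise RuntimeError("no available blocks")
    F = _destination_features(agent, world, available)
    logits = F.sum(axis=1)  # weights all 1
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return int(available[rng.choice(len(available), p=p)])


def destination_distribution(agent: AgentState, world: SimWorld) -> tuple[np.ndarray, np.ndarray]:
    """(available blocks, choice probabilities) -- the distribution SelectDest samples."""
    available = world.available
    F = _destination_features(agent, world, available)
    logits = F.sum(axis=1)
    logits -= logits.max()
    p = np.exp(logits)
    return available, p / p.sum()


def step(world: SimWorld, rng: np.random.Generator) -> SimWorld:
    """Advance all agents one timestep (mode logic, movement, destruction, reveals)."""
    env = world.environment
    reveals = []  # (agent_id, block, reward)
    for agent in world.agents:
        if agent.mode == "SelectDest":
            if len(world.destroyed) >= len(env.world_coords):
                continue
            agent.dest_block = select_destination(agent, world, rng)
            agent.seen_partners = {}
            agent.seen_success = set()
            agent.mode = "NavTo"
            continue
        if agent.mode == "NavTo":
            if agent.dest_block in world.destroyed:
                agent.mode = "SelectDest"
                continue
            dest_xy = env.world_coords[agent.dest_block]
            if np.allclose(agent.pos, dest_xy):
                agent.mode = "forage"
                agent.forage_k = FORAGE_STEPS
                continue
            moves = agent.pos[None, :] + _CARDINALS * MOVE_STEP
            d = np.linalg.norm(moves - dest_xy[None, :], axis=1)
            best = int(np.argmin(d))  # ties -> first in N,E,S,W order
            direction = _CARDINALS[best]
            agent.pos = moves[best]
            agent.heading = direction.copy()
            continue
        if agent.mode == "forage":
            agent.forage_k -= 1
            if agent.forage_k <= 0:
                block = agent.dest_block
                if block not in world.destroyed:
                    world.destroyed.add(block)
                    reward = int(env.reward_at(block))
                    agent.total_reward += reward
                    agent.belief = agent.belief.observe(env.world_coords[block], reward)
                    world.events.append((world.timestep * TIMESTEP_SECONDS, agent.agent_id, block, reward))
                    if reward:
                        reveals.append((agent.agent_id, block))
                agent.mode = "SelectDest"

    # observations after movement: partners in FOV, and reward reveals in FOV
    positions = np.stack([a.pos for a in world.agents])
    headings = np.stack([a.heading for a in world.agents])
    vis = visible_mask(positions, headings, positions)
    for i, agent in enumerate(world.agents):
        for j, other in enumerate(world.agents):
            if i != j and vis[i, j]:
                agent.seen_partners[j] = other.pos.copy()
    for owner, block in reveals:
        block_xy = env.world_coords[block]
        seen = visible_mask(positions, headings, block_xy[None, :])[:, 0]
        for i, agent in enumerate(world.agents):
            if i != owner and seen[i]:
                agent.seen_partners[owner] = block_xy.copy()
                agent.seen_success.add(owner)

    world.trace_pos.append(positions.copy())
    world.trace_heading.append(headings.copy())
    world.timestep += 1
    return world


@dataclass
class EpisodeResult:
    rewards: np.ndarray  # per agent
    events: list[tuple]
    trace_pos: np.ndarray | None = None  # (T, N, 2)
    trace_heading: np.ndarray | None = None
    agent_type: str = ""
    seed: int = 0


def run_episode(
    env: EnvironmentGrid,
    agent_type: str,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
    record: bool = False,
) -> EpisodeResult:
    """Run one homogeneous 4-agent episode; deterministic given seed."""
    rng = np.random.default_rng(seed)
    world = init_world(env, agent_type, rng)
    for _ in range(horizon):
        step(world, rng)
    return EpisodeResult(
        rewards=np.array([a.total_reward for a in world.agents]),
        events=world.events,
        trace_pos=np.stack(world.trace_pos) if record else None,
        trace_heading=np.stack(world.trace_heading) if record else None,
        agent_type=agent_type,
        seed=seed,
    )


def design_manifest(
    n_envs_per_type: int = 20,
    replicates: int = 100,
    agent_types: tuple[str, ...] = AGENT_TYPES,
) -> pd.DataFrame:
    """Enumerate the full factorial design without executing it.

    The study-scale design is 20 environments x 2 types x 100 replicates x 3
    agent strategies = 12,000 simulations.
    """
    rows = itertools.product(
        ("smooth", "random"), range(n_envs_per_type), agent_types, range(replicates)
    )
    return pd.DataFrame(rows, columns=["env_type", "env_index", "agent_type", "replicate"])


def run_design(
    n_envs_per_type: int = 20,
    replicates: int = 100,
    agent_types: tuple[str, ...] = AGENT_TYPES,
    horizon: int = DEFAULT_HORIZON,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the (possibly scaled-down) factorial design.

    Returns ``(results, summary)``: per-run per-agent total rewards, and mean
    reward per agent by environment type x agent type with normal-theory 95%
    CIs over runs.
    """
    manifest = design_manifest(n_envs_per_type, replicates, agent_types)
    envs = {
        ("smooth", i): sample_smooth_environment(seed=10_000 + i)
        for i in range(n_envs_per_type)
    }
    envs.update(
        {("random", i): sample_random_environment(seed=20_000 + i) for i in range(n_envs_per_type)}
    )
    rows = []
    for run_id, row in enumerate(manifest.itertuples(index=False)):
        env = envs[(row.env_type, row.env_index)]
        ep = run_episode(env, row.agent_type, horizon=horizon, seed=seed + 31 * run_id)
        for a, r in enumerate(ep.rewards):
            rows.append((row.env_type, row.agent_type, run_id, a, int(r)))
    results = pd.DataFrame(rows, columns=["env_type", "agent_type", "run", "agent", "total_reward"])
    per_run = results.groupby(["env_type", "agent_type", "run"])["total_reward"].mean().reset_index()
    summary = (
        per_run.groupby(["env_type", "agent_type"])["total_reward"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary["ci95_lo"] = summary["mean"] - 1.96 * summary["std"] / np.sqrt(summary["count"])
    summary["ci95_hi"] = summary["mean"] + 1.96 * summary["std"] / np.sqrt(summary["count"])
    return results, summary


def episode_to_session(result: EpisodeResult, env: EnvironmentGrid, config: dict | None = None):
    """Render a recorded episode into 20 Hz SessionLogs (linear upsampling)."""
    from forageworld import session as sess

    if result.trace_pos is None:
        raise ValueError("episode must be run with record=True")
    config = dict(config or {})
    T = result.trace_pos.shape[0]
    upsample = int(round(TIMESTEP_SECONDS / sess.TICK))
    n_ticks = T * upsample
    times = np.round(np.arange(n_ticks) * sess.TICK, 4)
    frames = []
    for a in range(result.trace_pos.shape[1]):
        coarse = result.trace_pos[:, a, :]
        fine = np.empty((n_ticks, 2))
        for d in range(2):
            fine[:, d] = np.interp(
                np.arange(n_ticks) / upsample, np.arange(T), coarse[:, d]
            )
        dxz = np.diff(fine, axis=0, prepend=fine[:1])
        hd = sess._heading_from_velocity(dxz, result.trace_heading[0, a])
        frames.append(
            pd.DataFrame(
                {"time": times, "player": a, "x": fine[:, 0], "z": fine[:, 1], "hx": hd[:, 0], "hz": hd[:, 1]}
            )
        )
    player_log = pd.concat(frames, ignore_index=True)
    map_log = sess._map_log_from_events(
        [(t, a, b, r) for (t, a, b, r) in result.events], env
    )
    vis = sess.derive_visibility(
        player_log, map_log, env,
        splash_duration=float(config.get("splash_duration", sess.DEFAULT_SPLASH_DURATION)),
    )
    meta = {
        "condition": "group",
        "env_type": env.env_type,
        "duration": float(n_ticks * sess.TICK),
        "dt": sess.TICK,
        "seed": result.seed,
        "mode": "agentsim",
        "agent_type": result.agent_type,
    }
    return sess.SessionLogs(player_log, map_log, vis, env, meta)
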