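"""Per-candidate block features for the sequential choice models.

Each block-destruction decision is predicted from the state of the world at the
moment the previous block was destroyed. For every remaining candidate block we
compute *asocial* features -- locality (inverse distance to the forager), block
visibility (inside the horizontal field of view), and GP reward prediction from
the forager's own outcome history -- and *social* features based on inverse
distance to the last observed location of peers who were visible during the
preceding inter-choice interval, split by whether they were observed acquiring
a reward (a visible splash).

Visibility is a permissive geometric approximation: a target is visible iff the
horizontal angle between the heading vector and the target direction is at most
half the 108.5-degree viewing angle, with no occlusion and unlimited range.

All non-binary feature columns are z-standardized within each choice (across
candidates); zero-variance columns standardize to all-zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from forageworld import gpclass

FOV_DEGREES = 108.5
#: Inverse distances are floored at one block (1 world unit) to bound weights.
DISTANCE_FLOOR = 1.0

ASOCIAL_FEATURES = ("locality", "visibility", "reward_prediction")
BINARY_FEATURES = ("visibility",)


@dataclass(frozen=True)
class Pose:
    """Horizontal position and unit heading vector of a player at one tick."""

    x: float
    z: float
    heading: np.ndarray  # (2,) unit vector

    def __post_init__(self):
        h = np.asarray(self.heading, dtype=float).ravel()
        norm = np.linalg.norm(h)
        if norm < 1e-12:
            raise ValueError("heading vector must be non-zero")
        if abs(norm - 1.0) > 1e-6:
            h = h / norm
        object.__setattr__(self, "heading", h)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.z])


def visible(pose: Pose, target: np.ndarray, fov_degrees: float = FOV_DEGREES) -> bool:
    """True iff the target lies within the horizontal field of view (inclusive)."""
    return bool(
        visible_mask(
            pose.position[None, :], pose.heading[None, :], np.asarray(target, float).reshape(1, 2)
        )[0, 0]
    )


def visible_mask(
    positions: np.ndarray,
    headings: np.ndarray,
    targets: np.ndarray,
    fov_degrees: float = FOV_DEGREES,
) -> np.ndarray:
    """Vectorized FOV test: (n_observers, n_targets) boolean matrix.

    A target coincident with the observer's position is treated as visible.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    headings = np.asarray(headings, dtype=float).reshape(-1, 2)
    norms = np.linalg.norm(headings, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length heading vector")
    headings = headings / norms[:, None]
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    diff = targets[None, :, :] - positions[:, None, :]  # (n_obs, n_tgt, 2)
    dist = np.linalg.norm(diff, axis=-1)
    cos_half = np.cos(np.deg2rad(fov_degrees) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("otk,ok->ot", diff, headings) / np.where(dist > 0, dist, np.inf)
    # inclusive boundary, with a hair of slack against roundoff at exactly fov/2
    return (cosang >= cos_half - 1e-12) | (dist == 0.0)


def inverse_distance(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """1 / max(d, 1 block) from each point to a reference location."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    d = np.linalg.norm(points - np.asarray(reference, dtype=float).ravel()[None, :], axis=1)
    return 1.0 / np.maximum(d, DISTANCE_FLOOR)


def compute_locality(player_pos: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Inverse distance from the player to each candidate block (raw, unstandardized)."""
    return inverse_distance(candidates, player_pos)


def compute_social_proximity(
    observed_positions: dict[int, np.ndarray],
    qualifying: list[int],
    candidates: np.ndarray,
    variant: str = "all",
) -> np.ndarray | dict[int, np.ndarray]:
    """Inverse distance from candidates to qualifying peers' last observed locations.

    ``observed_positions`` maps peer id to the position at the most recent tick
    the peer was inside the observer's FOV during the inter-choice interval.
    For ``all``/``successful``/``unsuccessful`` the centroid of qualifying
    peers is used; with no qualifying peer the column is all-zero (and is
    skipped by standardization). ``per_player`` returns one column per peer.
    """
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 2)
    if variant == "per_player":
        return {
            pid: (
                inverse_distance(candidates, observed_positions[pid])
                if pid in observed_positions and pid in qualifying
                else np.zeros(len(candidates))
            )
            for pid in sorted(observed_positions.keys() | set(qualifying))
        }
    qual = [p for p in qualifying if p in observed_positions]
    if not qual:
        return np.zeros(len(candidates))
    centroid = np.mean([observed_positions[p] for p in qual], axis=0)
    return inverse_distance(candidates, centroid)


def standardize_columns(
    columns: dict[str, np.ndarray],
    binary: tuple[str, ...] = BINARY_FEATURES,
) -> dict[str, np.ndarray]:
    """Z-standardize each non-binary column across candidates.

    Zero-variance (including all-zero social) columns map to all-zeros, never
    NaN. Idempotent: standardizing twice equals standardizing once.
    """
    out = {}
    for name, col in columns.items():
        col = np.asarray(col, dtype=float)
        if name in binary or any(name.startswith(b + "_") for b in binary):
            out[name] = col
            continue
        sd = col.std()
        out[name] = (col - col.mean()) / sd if sd > 1e-12 else np.zeros_like(col)
    return out


@dataclass
class ChoiceRecord:
    """One block-destruction decision with per-candidate feature columns.

    ``features`` holds standardized columns over the candidate blocks;
    ``chosen`` indexes the destroyed block among ``block_ids``; ``delta_t``
    maps adaptation clocks (``individual_reward``, ``social_observed_reward``)
    to the raw elapsed seconds since the last event of that type.
    """

    k: int
    time: float
    block_ids: np.ndarray
    features: dict[str, np.ndarray]
    chosen: int
    delta_t: dict[str, float] = field(default_factory=dict)
    delta_t_norm: dict[str, float] = field(default_factory=dict)

    @property
    def n_candidates(self) -> int:
        return len(self.block_ids)

    def matrix(self, feature_names: list[str]) -> np.ndarray:
        return np.column_stack([self.features[f] for f in feature_names])


def _interval_observations(session, player: int, t_prev: float, t_now: float):
    """Peers visible in (t_prev, t_now]: last observed positions, and who splashed."""
    vis = session.visibility_log
    win = vis[(vis["time"] > t_prev) & (vis["time"] <= t_now) & (vis["observer"] == player)]
    players_seen = win[win["kind"] == "player"]
    last_pos: dict[int, np.ndarray] = {}
    for pid, grp in players_seen.groupby("target"):
        row = grp.loc[grp["time"].idxmax()]
        last_pos[int(pid)] = np.array([row["x"], row["z"]])
    successful = set(int(p) for p in win.loc[win["kind"] == "splash", "target"].unique())
    return last_pos, successful


def assemble_choice_features(
    session,
    player: int,
    fov_degrees: float = FOV_DEGREES,
    lengthscale: float = gpclass.DEFAULT_LENGTHSCALE_WORLD,
    reward_feature: str = "probability",
) -> list[ChoiceRecord]:
    """Build one ChoiceRecord per modeled destruction decision of a player.

    The first destruction in a round is conditioned on, not modeled. The
    reward-prediction column uses only the player's own outcome history up to
    the previous destruction. ``reward_feature`` selects whether the column is
    the predictive probability (default) or the latent predictive mean
    (``"latent"``).
    """
    mlog = session.map_log.sort_values("time")
    own = mlog[mlog["player"] == player].reset_index(drop=True)
    if len(own) < 2:
        return []
    plog = session.player_log[session.player_log["player"] == player]
    block_xy = session.environment.world_coords
    records: list[ChoiceRecord] = []
    belief = gpclass.GPBeliefState(lengthscale=lengthscale)
    # observe the first destruction before modeling starts
    first = own.iloc[0]
    belief = belief.observe(np.array([first["x"], first["z"]]), float(first["reward"]))
    own_reward_times = own.loc[own["reward"] == 1, "time"].to_numpy()
    splash_seen = session.visibility_log
    splash_seen = splash_seen[(splash_seen["observer"] == player) & (splash_seen["kind"] == "splash")]
    solo = session.meta.get("condition") == "solo"

    for k in range(1, len(own)):
        t_k = float(own.iloc[k - 1]["time"])  # state of the world at the k-th destruction
        t_next = float(own.iloc[k]["time"])
        destroyed = set(
            int(b) for b in session.available_mask_times(t_k, player=player if solo else None)
        )
        candidates = np.array(
            [b for b in range(len(block_xy)) if b not in destroyed], dtype=int
        )
        chosen_block = int(own.iloc[k]["block"])
        if chosen_block not in candidates:
            raise ValueError(f"chosen block {chosen_block} not among candidates at k={k}")
        cand_xy = block_xy[candidates]

        prow = plog.iloc[(plog["time"] - t_k).abs().to_numpy().argmin()]
        pose = Pose(prow["x"], prow["z"], np.array([prow["hx"], prow["hz"]]))

        cols: dict[str, np.ndarray] = {
            "locality": compute_locality(pose.position, cand_xy),
            "visibility": visible_mask(
                pose.position[None, :], pose.heading[None, :], cand_xy, fov_degrees
            )[0].astype(float),
        }
        preds = gpclass.predict_many(belief, cand_xy)
        if reward_feature == "latent":
            Ks = gpclass._gram(belief.X_k, cand_xy, belief.lengthscale) if belief.n_obs else None
            cols["reward_prediction"] = (
                Ks.T @ (belief.r_k - 1.0 / (1.0 + np.exp(-(belief.z_hat + belief.z0))))
                if Ks is not None
                else np.zeros(len(candidates))
            )
        else:
            cols["reward_prediction"] = preds

        t_prev = float(own.iloc[k - 2]["time"]) if k >= 2 else 0.0
        last_pos, successful = _interval_observations(session, player, t_prev, t_k)
        seen = sorted(last_pos)
        cols["social_proximity"] = compute_social_proximity(last_pos, seen, cand_xy, "all")
        cols["successful_proximity"] = compute_social_proximity(
            last_pos, [p for p in seen if p in successful], cand_xy, "successful"
        )
        cols["unsuccessful_proximity"] = compute_social_proximity(
            last_pos, [p for p in seen if p not in successful], cand_xy, "unsuccessful"
        )
        for pid in session.players:
            if pid == player:
                continue
            cols[f"proximity_p{pid}"] = (
                inverse_distance(cand_xy, last_pos[pid]) if pid in last_pos else np.zeros(len(candidates))
            )

        prior_rewards = own_reward_times[own_reward_times <= t_k]
        dt_ind = t_k - (prior_rewards[-1] if len(prior_rewards) else 0.0)
        prior_splash = splash_seen[splash_seen["time"] <= t_k]
        dt_soc = t_k - (float(prior_splash["time"].max()) if len(prior_splash) else 0.0)

        records.append(
            ChoiceRecord(
                k=k,
                time=t_next,
                block_ids=candidates,
                features=standardize_columns(cols),
                chosen=int(np.where(candidates == chosen_block)[0][0]),
                delta_t={"individual_reward": dt_ind, "social_observed_reward": dt_soc},
            )
        )
        belief = belief.observe(
            np.array([own.iloc[k]["x"], own.iloc[k]["z"]]), float(own.iloc[k]["reward"])
        )
    return records
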