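"""Time-lagged correlation analysis with cluster-based permutation testing.

For a pair of per-round time series (e.g., a player's reward vector and their
spatial proximity to peers, both at 20 Hz), the second series is iteratively
time-lagged from -20 s to +20 s and a Pearson correlation is computed on the
overlapping region at every offset, then Fisher z-transformed. Effects at
negative offsets mean V1 predicts future V2; positive offsets mean V2 predicts
future V1 (when V1 is reward: rewards predicting behavior vs. behavior
predicting rewards).

Raw lagged correlations carry bias from autocorrelation and task structure, so
each is chance-corrected by subtracting the mean z over correlations with
temporally permuted copies of V2 (default 100 permutations).

Population-level significance uses a cluster permutation procedure: a
one-sample t-test across individual corrected series at each offset marks
significant time points; temporally contiguous same-sign runs form clusters;
a sign-flip null (randomly flipping the sign of each corrected value) yields
the distribution of the maximum null cluster duration, and only observed
clusters longer than the null's 95th percentile survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

TICK = 0.05
MAX_OFFSET_SECONDS = 20.0
Z_CLIP = 1.0 - 1e-6


def default_offsets(step_seconds: float = TICK, max_offset: float = MAX_OFFSET_SECONDS) -> np.ndarray:
    """Symmetric offsets in seconds, native tick resolution by default."""
    n = int(round(max_offset / step_seconds))
    return np.arange(-n, n + 1) * step_seconds


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def _corr_at_offset(v1: np.ndarray, v2: np.ndarray, k: int) -> float:
    """Pearson correlation of v1[t] with v2[t+k] on the overlap; NaN if constant."""
    if k >= 0:
        a, b = v1[: len(v1) - k or None], v2[k:]
    else:
        a, b = v1[-k:], v2[: len(v2) + k]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def lagged_correlation(
    v1: np.ndarray,
    v2: np.ndarray,
    offsets: np.ndarray | None = None,
    step_seconds: float = TICK,
) -> np.ndarray:
    """Fisher-z lagged correlations of two equal-length 20 Hz series.

    ``offsets`` are in seconds (converted to whole ticks); non-overlapping
    regions are omitted from each correlation. Constant overlap windows give
    NaN (recorded as missing).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("series must have equal length")
    if offsets is None:
        offsets = default_offsets(step_seconds)
    ticks = np.round(np.asarray(offsets) / TICK).astype(int)
    if np.max(np.abs(ticks)) >= len(v1):
        raise ValueError("series shorter than the maximum offset")
    return _fisher_z(np.array([_corr_at_offset(v1, v2, k) for k in ticks]))


def chance_correct(
    v1: np.ndarray,
    v2: np.ndarray,
    offsets: np.ndarray | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Chance-corrected lagged correlations: z minus the mean z over
    order-permuted copies of V2."""
    if offsets is None:
        offsets = default_offsets()
    observed = lagged_correlation(v1, v2, offsets)
    rng = np.random.default_rng(seed)
    v2 = np.asarray(v2, dtype=float)
    null = np.zeros((n_perm, len(offsets)))
    for p in range(n_perm):
        null[p] = lagged_correlation(v1, rng.permutation(v2), offsets)
    return observed - np.nanmean(null, axis=0)


@dataclass
class Cluster:
    start: float  # offset seconds (inclusive)
    end: float
    sign: int
    duration: float


@dataclass
class ClusterResult:
    """Surviving clusters plus the null cluster-duration summary."""

    clusters: list[Cluster]
    threshold: float  # minimum surviving duration (seconds), null 95th percentile
    null_max_durations: np.ndarray = field(repr=False, default=None)
    n_perm: int = 0
    offsets: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_perm": self.n_perm,
            "clusters": [
                {"start": c.start, "end": c.end, "sign": c.sign, "duration": c.duration}
                for c in self.clusters
            ],
        }


def _cluster_runs(sig: np.ndarray, sign: np.ndarray):
    """Maximal runs of significant offsets sharing a t-statistic sign."""
    runs = []
    i = 0
    n = len(sig)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        runs.append((i, j, int(sign[i])))
        i = j + 1
    return runs


def _max_run_duration(tstats: np.ndarray, crit: float, step: float) -> float:
    sig = np.abs(tstats) > crit
    best = 0
    i = 0
    n = len(sig)
    sign = np.sign(tstats)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        best = max(best, j - i + 1)
        i = j + 1
    return best * step


def cluster_mass_test(
    corrected: np.ndarray,
    offsets: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterResult:
    """Find temporally contiguous significant clusters that beat a sign-flip null.

    ``corrected`` is an (individuals x offsets) matrix of chance-corrected z
    values. At each offset a two-sided one-sample t-test (alpha) across
    individuals marks significance; contiguous same-sign runs form clusters.
    The null distribution of the maximum cluster duration is built by randomly
    flipping the sign of every value; observed clusters survive only if their
    duration strictly exceeds the null's 95th percentile (strict exceedance
    keeps the family-wise error at the nominal level with discrete durations).
    """
    X = np.asarray(corrected, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 individual series")
    offsets = np.asarray(offsets, dtype=float)
    step = float(np.median(np.diff(offsets))) if len(offsets) > 1 else TICK
    n, m = X.shape
    crit = stats.t.ppf(1 - alpha / 2, df=n - 1)

    def tstats(mat: np.ndarray) -> np.ndarray:
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // (n * m))))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        flips = rng.choice([-1.0, 1.0], size=(c, n, m))
        flipped = flips * X[None, :, :]
        means = flipped.mean(axis=1)
        sds = flipped.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ts = np.where(sds > 0, means / (sds / np.sqrt(n)), 0.0)
        for i in range(c):
            null_max[done + i] = _max_run_duration(ts[i], crit, step)
        done += c
    threshold = float(np.quantile(null_max, 0.95))

    t_obs = tstats(X)
    sig = np.abs(t_obs) > crit
    clusters = []
    for i, j, sgn in _cluster_runs(sig, np.sign(t_obs)):
        duration = (j - i + 1) * step
        if duration > threshold:
            clusters.append(
                Cluster(start=float(offsets[i]), end=float(offsets[j]), sign=sgn, duration=duration)
            )
    return ClusterResult(
        clusters=clusters,
        threshold=threshold,
        null_max_durations=null_max,
        n_perm=n_perm,
        offsets=offsets,
    )


# ---------------------------------------------------------------------------
# session-level convenience


def session_series(session) -> dict[int, dict[str, np.ndarray]]:
    """Per-player 20 Hz series: reward, proximity, visible peers, observers.

    Reward is a binary event vector (1 at rewarded-destruction ticks);
    proximity is the average inverse distance to all other players.
    """
    times, pos, _ = session.positions_wide()
    players = session.players
    n = len(times)
    out: dict[int, dict[str, np.ndarray]] = {}
    vis = session.visibility_log
    vis_players = vis[vis["kind"] == "player"]
    for idx, p in enumerate(players):
        reward = np.zeros(n)
        own = session.map_log[(session.map_log["player"] == p) & (session.map_log["reward"] == 1)]
        for t in own["time"]:
            reward[np.argmin(np.abs(times - t))] = 1.0
        others = [k for k in range(len(players)) if k != idx]
        d = np.linalg.norm(pos[:, [idx], :] - pos[:, others, :], axis=2)
        proximity = (1.0 / np.maximum(d, 1.0)).mean(axis=1)
        seen = vis_players[vis_players["observer"] == p].groupby("time")["target"].nunique()
        observers = vis_players[vis_players["target"] == p].groupby("time")["observer"].nunique()
        n_visible = np.zeros(n)
        n_observers = np.zeros(n)
        tidx = {round(t, 4): i for i, t in enumerate(times)}
        for t, c in seen.items():
            i = tidx.get(round(t, 4))
            if i is not None:
                n_visible[i] = c
        for t, c in observers.items():
            i = tidx.get(round(t, 4))
            if i is not None:
                n_observers[i] = c
        out[p] = {
            "reward": reward,
            "proximity": proximity,
            "n_visible_peers": n_visible,
            "n_observers": n_observers,
        }
    return out


def group_minus_solo(corrected_group: np.ndarray, corrected_solo: np.ndarray) -> np.ndarray:
    """Contrast corrected series before cluster testing (group - solo baseline)."""
    return np.asarray(corrected_group) - np.asarray(corrected_solo)
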