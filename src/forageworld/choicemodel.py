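"""Softmax sequential-choice models of block destruction.

Each destruction decision is a categorical choice among the remaining blocks,
with probability proportional to exp(f . w) for per-candidate feature vectors
f and weights w. *Static* models keep w fixed within a round; *dynamic* models
let selected weights drift linearly with the normalized elapsed time since the
last reward on an adaptation clock,

    w_eff = w + alpha * dt_norm,

where the clock is either the forager's own last reward (``individual_reward``)
or the last socially observed reward, i.e. visible splash
(``social_observed_reward``). The registry covers eight variants: four static
(Asocial, Unbiased, SuccessBiased, PlayerSpecific) and four dynamic (ARS,
Critical, Conditional, ARSCond). ARS adapts locality on the individual clock
(area-restricted search); Critical adapts reward prediction on the social
clock; Conditional adapts the success-biased proximity weights on the
individual clock; ARSCond combines ARS and Conditional.

Elapsed times are z-standardized across all choices in the fitted dataset so
that adaptation slopes are comparable in magnitude to the static weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from forageworld.features import ChoiceRecord

CLOCK_INDIVIDUAL = "individual_reward"
CLOCK_SOCIAL = "social_observed_reward"


@dataclass(frozen=True)
class ModelSpec:
    """A named feature set plus the mapping of features to adaptation clocks."""

    name: str
    feature_set: tuple[str, ...]
    dynamic_map: dict[str, str] = field(default_factory=dict)

    @property
    def is_dynamic(self) -> bool:
        return bool(self.dynamic_map)

    def resolve_features(self, record: ChoiceRecord) -> list[str]:
        """Expand the ``player_specific`` placeholder into concrete peer columns."""
        out = []
        for f in self.feature_set:
            if f == "player_specific":
                out.extend(sorted(c for c in record.features if c.startswith("proximity_p")))
            else:
                out.append(f)
        return out

    def parameter_names(self, record: ChoiceRecord | None = None) -> list[str]:
        feats = self.resolve_features(record) if record is not None else list(self.feature_set)
        return [f"w_{f}" for f in feats] + [f"alpha_{f}" for f in self.dynamic_map]


_ASOCIAL = ("locality", "visibility", "reward_prediction")
_SUCCESS = _ASOCIAL + ("successful_proximity", "unsuccessful_proximity")

MODEL_SPECS: dict[str, ModelSpec] = {
    "Asocial": ModelSpec("Asocial", _ASOCIAL),
    "Unbiased": ModelSpec("Unbiased", _ASOCIAL + ("social_proximity",)),
    "SuccessBiased": ModelSpec("SuccessBiased", _SUCCESS),
    "PlayerSpecific": ModelSpec("PlayerSpecific", _ASOCIAL + ("player_specific",)),
    "ARS": ModelSpec("ARS", _ASOCIAL, {"locality": CLOCK_INDIVIDUAL}),
    "Critical": ModelSpec("Critical", _SUCCESS, {"reward_prediction": CLOCK_SOCIAL}),
    "Conditional": ModelSpec(
        "Conditional",
        _SUCCESS,
        {"successful_proximity": CLOCK_INDIVIDUAL, "unsuccessful_proximity": CLOCK_INDIVIDUAL},
    ),
    "ARSCond": ModelSpec(
        "ARSCond",
        _SUCCESS,
        {
            "locality": CLOCK_INDIVIDUAL,
            "successful_proximity": CLOCK_INDIVIDUAL,
            "unsuccessful_proximity": CLOCK_INDIVIDUAL,
        },
    ),
}


@dataclass
class WeightVector:
    """Static weights per feature plus adaptation slopes per dynamic feature."""

    w: dict[str, float]
    alpha: dict[str, float] = field(default_factory=dict)

    def to_array(self, spec: ModelSpec, record: ChoiceRecord | None = None) -> np.ndarray:
        feats = spec.resolve_features(record) if record is not None else list(spec.feature_set)
        return np.array([self.w[f] for f in feats] + [self.alpha[f] for f in spec.dynamic_map])

    @classmethod
    def from_array(cls, theta: np.ndarray, spec: ModelSpec, record: ChoiceRecord | None = None) -> "WeightVector":
        feats = spec.resolve_features(record) if record is not None else list(spec.feature_set)
        n = len(feats)
        return cls(
            w=dict(zip(feats, theta[:n])),
            alpha=dict(zip(spec.dynamic_map, theta[n:])),
        )


def dynamic_weight(w: float, alpha: float, delta_t_normalized: float) -> float:
    """Effective weight under linear adaptation: w + alpha * normalized elapsed time."""
    return w + alpha * delta_t_normalized


def normalize_delta_t(records: list[ChoiceRecord]) -> None:
    """Z-standardize each clock's raw elapsed times across all choices, in place.

    With fewer than two choices (or zero variance) the normalized value is 0.
    """
    if not records:
        return
    clocks = set().union(*(r.delta_t.keys() for r in records))
    for clock in clocks:
        vals = np.array([r.delta_t[clock] for r in records if clock in r.delta_t])
        mu, sd = vals.mean(), vals.std()
        for r in records:
            if clock in r.delta_t:
                r.delta_t_norm[clock] = float((r.delta_t[clock] - mu) / sd) if sd > 1e-12 else 0.0


def effective_weights(
    spec: ModelSpec, weights: WeightVector, record: ChoiceRecord
) -> np.ndarray:
    feats = spec.resolve_features(record)
    w = np.array([weights.w[f] for f in feats])
    for i, f in enumerate(feats):
        if f in spec.dynamic_map:
            clock = spec.dynamic_map[f]
            w[i] = dynamic_weight(w[i], weights.alpha[f], record.delta_t_norm.get(clock, 0.0))
    return w


def choice_logprobs(spec: ModelSpec, weights: WeightVector, record: ChoiceRecord) -> np.ndarray:
    """Log softmax probabilities over the candidate blocks of one choice."""
    F = record.matrix(spec.resolve_features(record))
    logits = F @ effective_weights(spec, weights, record)
    return logits - logsumexp(logits)


def choice_loglikelihood(
    records: list[ChoiceRecord], spec: ModelSpec, weights: WeightVector
) -> float:
    """Sum of log softmax probabilities of the chosen blocks.

    Requires ``normalize_delta_t`` to have been applied for dynamic models
    (records with missing normalized clocks fall back to 0).
    """
    total = 0.0
    for r in records:
        if not (0 <= r.chosen < r.n_candidates):
            raise ValueError(f"chosen index {r.chosen} outside candidate set at k={r.k}")
        total += float(choice_logprobs(spec, weights, r)[r.chosen])
    return total


def simulate_choices(
    feature_records: list[ChoiceRecord],
    spec: ModelSpec,
    weights: WeightVector,
    seed: int,
) -> list[ChoiceRecord]:
    """Sample each choice from the softmax distribution; returns records with
    ``chosen`` overwritten. Deterministic given seed."""
    rng = np.random.default_rng(seed)
    out = []
    for r in feature_records:
        p = np.exp(choice_logprobs(spec, weights, r))
        p = p / p.sum()
        chosen = int(rng.choice(r.n_candidates, p=p))
        out.append(
            ChoiceRecord(
                k=r.k,
                time=r.time,
                block_ids=r.block_ids,
                features=r.features,
                chosen=chosen,
                delta_t=dict(r.delta_t),
                delta_t_norm=dict(r.delta_t_norm),
            )
        )
    return out


def synthesize_records(
    n_choices: int,
    n_candidates: int,
    seed: int,
    n_peers: int = 3,
    p_social_defined: float = 0.7,
) -> list[ChoiceRecord]:
    """Generate standalone feature records with the study's column structure.

    Used for parameter- and model-recovery simulations: columns are random but
    standardized exactly as real features would be (binary visibility; social
    columns all-zero with probability ``1 - p_social_defined``, mimicking
    choices with no visible or no successful peers). Elapsed-time clocks are
    drawn from an exponential renewal process and then normalized.
    """
    from forageworld.features import standardize_columns

    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_choices):
        cols = {
            "locality": 1.0 / np.maximum(rng.uniform(1, 30, n_candidates), 1.0),
            "visibility": (rng.random(n_candidates) < 0.5).astype(float),
            "reward_prediction": np.clip(0.25 + 0.15 * rng.standard_normal(n_candidates), 0.01, 0.99),
        }
        for name in ("social_proximity", "successful_proximity", "unsuccessful_proximity"):
            if rng.random() < p_social_defined:
                cols[name] = 1.0 / np.maximum(rng.uniform(1, 30, n_candidates), 1.0)
            else:
                cols[name] = np.zeros(n_candidates)
        for pid in range(1, n_peers + 1):
            cols[f"proximity_p{pid}"] = (
                1.0 / np.maximum(rng.uniform(1, 30, n_candidates), 1.0)
                if rng.random() < p_social_defined
                else np.zeros(n_candidates)
            )
        records.append(
            ChoiceRecord(
                k=k + 1,
                time=float(k) * 3.0,
                block_ids=np.arange(n_candidates),
                features=standardize_columns(cols),
                chosen=0,
                delta_t={
                    CLOCK_INDIVIDUAL: float(rng.exponential(8.0)),
                    CLOCK_SOCIAL: float(rng.exponential(8.0)),
                },
            )
        )
    normalize_delta_t(records)
    return records
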