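"""Gaussian-process binary classification for reward prediction.

A forager's belief about where rewards are is modeled as GP binary
classification over block locations: the probability that destroying block
``x`` yields a reward is a logistic sigmoid of a latent function ``z``,
``p(r=1|z) = S(z)``. The prior mean ``z0 = log(0.25/0.75)`` encodes the true
25% base rate, so with no observations the predictive probability is exactly
0.25 everywhere. Spatial generalization comes from an RBF kernel (lengthscale
in world units, default sqrt(48)).

The intractable posterior over the latent values at observed blocks is
replaced by a Laplace (Gaussian) approximation around the posterior mode,
found by Newton/IRLS iteration. Predictive latent mean and variance at a
target block follow the standard GP conditional, and the predictive reward
probability applies the probit moderation

    p(r=1 | D) ~= S(z0 + mu_* (1 + pi sigma_*^2 / 8)^(-1/2)),

i.e. the latent algebra is carried out in centered space (z - z0) and the
prior mean is added back after the variance moderation, which preserves the
exact 0.25 prior limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: Prior mean of the latent: sigmoid(Z0) = 0.25, the true reward base rate.
Z0 = float(np.log(0.25 / 0.75))
#: Latent noise variance (matches the environment-generating process).
NOISE_VARIANCE = 1e-4
#: Cognitive-model lengthscale in world units.
DEFAULT_LENGTHSCALE_WORLD = float(np.sqrt(48.0))
JITTER = 1e-8

MODE_TOL = 1e-6
MODE_MAX_ITER = 100


class LaplaceConvergenceError(RuntimeError):
    """Posterior-mode iteration failed to converge within the iteration budget."""


def rbf_kernel(x: np.ndarray, x_prime: np.ndarray, lengthscale: float) -> float:
    """RBF kernel value exp(-||x - x'||^2 / (2 l^2)); symmetric, in (0, 1]."""
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    return float(np.exp(-np.sum((x - x_prime) ** 2) / (2.0 * lengthscale**2)))


def _gram(A: np.ndarray, B: np.ndarray, lengthscale: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * lengthscale**2))


@dataclass
class LatentPrediction:
    """Predictive latent mean/variance at a target and the squashed reward probability."""

    mu: float
    sigma2: float
    prob: float


@dataclass
class GPBeliefState:
    """Kernel matrix, observations, and Laplace posterior mode for reward prediction.

    ``z_hat`` stores the posterior mode of the *centered* latent (z - z0);
    the prior mean is reapplied inside the sigmoid.
    """

    lengthscale: float = DEFAULT_LENGTHSCALE_WORLD
    z0: float = Z0
    sigma2_noise: float = NOISE_VARIANCE
    X_k: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    r_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    K: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    z_hat: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: bool = True

    def __post_init__(self):
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be positive")
        self.X_k = np.asarray(self.X_k, dtype=float).reshape(-1, 2)
        self.r_k = np.asarray(self.r_k, dtype=float).ravel()

    @property
    def n_obs(self) -> int:
        return len(self.r_k)

    @property
    def W(self) -> np.ndarray:
        """Diagonal of the Hessian of the Bernoulli log-likelihood at the mode."""
        s = expit(self.z_hat + self.z0)
        return s * (1.0 - s)

    def observe(self, x: np.ndarray, r: float) -> "GPBeliefState":
        """Return a new belief state with one (location, reward) observation added."""
        X = np.vstack([self.X_k, np.asarray(x, dtype=float).reshape(1, 2)])
        rk = np.append(self.r_k, float(r))
        state = GPBeliefState(
            lengthscale=self.lengthscale,
            z0=self.z0,
            sigma2_noise=self.sigma2_noise,
            X_k=X,
            r_k=rk,
        )
        state.K = _gram(X, X, self.lengthscale)
        return laplace_mode(state)

    def to_dict(self) -> dict:
        return {
            "lengthscale": self.lengthscale,
            "z0": self.z0,
            "sigma2_noise": self.sigma2_noise,
            "X_k": self.X_k.tolist(),
            "r_k": self.r_k.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPBeliefState":
        state = cls(
            lengthscale=d["lengthscale"],
            z0=d.get("z0", Z0),
            sigma2_noise=d.get("sigma2_noise", NOISE_VARIANCE),
        )
        for x, r in zip(d["X_k"], d["r_k"]):
            state = state.observe(np.asarray(x), r)
        return state


def belief_from_history(
    X: np.ndarray,
    r: np.ndarray,
    lengthscale: float = DEFAULT_LENGTHSCALE_WORLD,
) -> GPBeliefState:
    """Build a belief state from an observation history (world coords, rewards)."""
    X = np.asarray(X, dtype=float).reshape(-1, 2)
    r = np.asarray(r, dtype=float).ravel()
    state = GPBeliefState(lengthscale=lengthscale, X_k=X, r_k=r)
    if len(r) == 0:
        return state
    state.K = _gram(X, X, lengthscale)
    return laplace_mode(state)


def laplace_mode(
    state: GPBeliefState,
    tol: float = MODE_TOL,
    max_iter: int = MODE_MAX_ITER,
) -> GPBeliefState:
    """Find the Laplace posterior mode of the centered latent by Newton/IRLS.

    Iterates z_new = K_z (I + W K_z)^{-1} (W z + r - S(z + z0)) with
    K_z = K + sigma^2 I until the mode changes by less than ``tol``; the fixed
    point satisfies the self-consistency z = K_z (r - S(z + z0)).
    """
    if state.n_obs == 0:
        raise ValueError("laplace_mode requires at least one observation")
    n = state.n_obs
    Kz = state.K + (state.sigma2_noise + JITTER) * np.eye(n)
    z = np.zeros(n)
    for _ in range(max_iter):
        s = expit(z + state.z0)
        w = s * (1.0 - s)
        B = np.eye(n) + w[:, None] * Kz
        z_new = Kz @ np.linalg.solve(B, w * z + state.r_k - s)
        if np.max(np.abs(z_new - z)) < tol:
            state.z_hat = z_new
            state.converged = True
            return state
        z = z_new
    state.z_hat = z
    state.converged = False
    raise LaplaceConvergenceError(
        f"posterior mode did not converge in {max_iter} iterations"
    )


def predict_reward_probability(state: GPBeliefState, target: np.ndarray) -> LatentPrediction:
    """Probit-moderated predictive reward probability at a target location.

    With zero observations this returns sigmoid(z0) = 0.25 exactly; far from
    all observations the kernel vector vanishes and the prediction reverts to
    the prior.
    """
    target = np.asarray(target, dtype=float).ravel()
    if state.n_obs == 0:
        return LatentPrediction(mu=0.0, sigma2=1.0, prob=float(expit(state.z0)))
    k_star = _gram(state.X_k, target.reshape(1, 2), state.lengthscale).ravel()
    mu = float(k_star @ (state.r_k - expit(state.z_hat + state.z0)))
    W = state.W
    M = np.diag(1.0 / W) + state.K + (state.sigma2_noise + JITTER) * np.eye(state.n_obs)
    sigma2 = float(1.0 - k_star @ np.linalg.solve(M, k_star))
    sigma2 = max(sigma2, 0.0)
    prob = float(expit(state.z0 + mu / np.sqrt(1.0 + np.pi * sigma2 / 8.0)))
    return LatentPrediction(mu=mu, sigma2=sigma2, prob=prob)


def predict_many(state: GPBeliefState, targets: np.ndarray) -> np.ndarray:
    """Vectorized predictive reward probabilities at an (n, 2) array of targets."""
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    if state.n_obs == 0:
        return np.full(len(targets), float(expit(state.z0)))
    Ks = _gram(state.X_k, targets, state.lengthscale)  # (k, n)
    mu = Ks.T @ (state.r_k - expit(state.z_hat + state.z0))
    W = state.W
    M = np.diag(1.0 / W) + state.K + (state.sigma2_noise + JITTER) * np.eye(state.n_obs)
    sigma2 = 1.0 - np.einsum("kn,kn->n", Ks, np.linalg.solve(M, Ks))
    sigma2 = np.clip(sigma2, 0.0, None)
    return expit(state.z0 + mu / np.sqrt(1.0 + np.pi * sigma2 / 8.0))
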