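import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

from forageworld import gpclass


def test_rbf_kernel_values():
    assert gpclass.rbf_kernel([1.0, 2.0], [1.0, 2.0], 5.0) == pytest.approx(1.0)
    l = 3.7
    assert gpclass.rbf_kernel([0.0, 0.0], [l, 0.0], l) == pytest.approx(np.exp(-0.5))
    with pytest.raises(ValueError):
        gpclass.rbf_kernel([0, 0], [1, 1], 0.0)


def test_rbf_gram_positive_semidefinite():
    rng = np.random.default_rng(0)
    for _ in range(10):
        X = rng.uniform(0, 60, size=(5, 2))
        K = gpclass._gram(X, X, gpclass.DEFAULT_LENGTHSCALE_WORLD)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
        assert np.allclose(K, K.T) and np.allclose(np.diag(K), 1.0)


def test_zero_observations_predict_prior():
    state = gpclass.GPBeliefState()
    for target in ([0, 0], [30, 12], [500, -500]):
        pred = gpclass.predict_reward_probability(state, np.array(target, dtype=float))
        assert pred.prob == pytest.approx(0.25)


def test_single_observation_moves_mode():
    state = gpclass.GPBeliefState()
    up = state.observe(np.array([10.0, 10.0]), 1.0)
    down = state.observe(np.array([10.0, 10.0]), 0.0)
    assert up.z_hat[0] > 0  # centered latent above prior mean after a reward
    assert down.z_hat[0] < 0


def test_mode_self_consistency():
    """At the converged mode, z = K_z (r - S(z + z0)) holds to tight tolerance."""
    rng = np.random.default_rng(1)
    state = gpclass.GPBeliefState()
    for _ in range(4):
        state = state.observe(rng.uniform(0, 30, 2), float(rng.integers(0, 2)))
    Kz = state.K + (state.sigma2_noise + gpclass.JITTER) * np.eye(state.n_obs)
    resid = state.z_hat - Kz @ (state.r_k - expit(state.z_hat + state.z0))
    assert np.max(np.abs(resid)) < 1e-6


def test_far_target_reverts_to_prior():
    state = gpclass.GPBeliefState().observe(np.array([0.0, 0.0]), 1.0)
    pred = gpclass.predict_reward_probability(state, np.array([1000.0, 1000.0]))
    assert pred.prob == pytest.approx(0.25, abs=1e-9)


def test_observed_locations_ordered_around_prior():
    state = gpclass.GPBeliefState()
    state = state.observe(np.array([0.0, 0.0]), 1.0)
    state = state.observe(np.array([40.0, 40.0]), 0.0)
    p_hit = gpclass.predict_reward_probability(state, np.array([0.0, 0.0])).prob
    p_miss = gpclass.predict_reward_probability(state, np.array([40.0, 40.0])).prob
    assert p_hit > 0.25 > p_miss


def test_flipping_observation_monotone():
    """Turning a miss into a hit never meaningfully decreases the predictive
    probability anywhere.

    The exact posterior is monotone in each outcome; the Laplace/probit
    approximation preserves this only up to a small remainder (the mode shift
    at the other observations partially offsets the flip), so the check allows
    a 1e-3 slack.
    """
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 30, size=(3, 2))
    targets = rng.uniform(0, 30, size=(20, 2))
    for flip in range(3):
        r0 = np.array([0.0, 1.0, 0.0])
        r1 = r0.copy()
        r0[flip], r1[flip] = 0.0, 1.0
        s0 = gpclass.belief_from_history(X, r0)
        s1 = gpclass.belief_from_history(X, r1)
        assert np.all(gpclass.predict_many(s1, targets) >= gpclass.predict_many(s0, targets) - 1e-3)


def test_predictive_variance_shrinks_with_nearby_data():
    target = np.array([10.0, 10.0])
    state = gpclass.GPBeliefState().observe(np.array([12.0, 10.0]), 1.0)
    v1 = gpclass.predict_reward_probability(state, target).sigma2
    state2 = state.observe(np.array([9.0, 11.0]), 0.0)
    v2 = gpclass.predict_reward_probability(state2, target).sigma2
    assert v2 <= v1 <= 1.0


def test_nonconvergence_raises():
    state = gpclass.GPBeliefState(X_k=np.array([[0.0, 0.0]]), r_k=np.array([1.0]))
    state.K = np.array([[1.0]])
    with pytest.raises(gpclass.LaplaceConvergenceError):
        gpclass.laplace_mode(state, max_iter=1)


def test_serialization_round_trip():
    rng = np.random.default_rng(3)
    state = gpclass.GPBeliefState()
    for _ in range(3):
        state = state.observe(rng.uniform(0, 30, 2), float(rng.integers(0, 2)))
    back = gpclass.GPBeliefState.from_dict(state.to_dict())
    t = np.array([5.0, 5.0])
    assert gpclass.predict_reward_probability(back, t).prob == pytest.approx(
        gpclass.predict_reward_probability(state, t).prob
    )


# ---------------------------------------------------------------------------
# quadrature oracle for the Laplace approximation


def quadrature_reference(state: gpclass.GPBeliefState, target: np.ndarray, n_nodes: int = 41) -> float:
    """Exact posterior moments of the centered latent via tensor Gauss-Hermite
    quadrature, squashed through the same probit moderation as the package.

    Independent of the Laplace code path: integrates the Bernoulli likelihood
    against the exact latent prior on the observed blocks.
    """
    k = state.n_obs
    Kz = state.K + (state.sigma2_noise + gpclass.JITTER) * np.eye(k)
    L = np.linalg.cholesky(Kz)
    nodes, wts = hermegauss(n_nodes)
    grids = np.meshgrid(*([nodes] * k), indexing="ij")
    U = np.stack([g.ravel() for g in grids])
    W = np.ones(U.shape[1])
    idx = np.unravel_index(np.arange(U.shape[1]), (n_nodes,) * k)
    for i in range(k):
        W = W * wts[idx[i]]
    C = L @ U  # centered latent draws at observed blocks
    lik = np.prod(
        np.where(state.r_k[:, None] == 1, expit(C + state.z0), 1 - expit(C + state.z0)), axis=0
    )
    w = W * lik
    w = w / w.sum()
    ks = gpclass._gram(state.X_k, np.asarray(target, float).reshape(1, 2), state.lengthscale).ravel()
    a = np.linalg.solve(Kz, ks)
    m = a @ C
    v = 1.0 + state.sigma2_noise - ks @ a
    mu = float(w @ m)
    var = float(v + w @ (m - mu) ** 2)
    return float(expit(state.z0 + mu / np.sqrt(1 + np.pi * var / 8)))


def test_laplace_predictive_matches_quadrature_oracle():
    """Laplace-approximated predictive within 0.01 of the exact-moments
    quadrature reference for 1-3 observations."""
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(25):
        k = int(rng.integers(1, 4))
        X = rng.uniform(0, 60, size=(k, 2))
        r = rng.integers(0, 2, size=k).astype(float)
        state = gpclass.belief_from_history(X, r)
        target = rng.uniform(0, 60, 2) if rng.random() < 0.5 else X[0] + rng.normal(0, 3, 2)
        got = gpclass.predict_reward_probability(state, target).prob
        want = quadrature_reference(state, target)
        worst = max(worst, abs(got - want))
    assert worst < 0.01
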