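"""Weight estimation and Bayesian model selection for the choice models.

Weights are estimated hierarchically: per-individual weights are partially
pooled toward population means under weakly informative priors -- standard
normal on population means, Exponential(1) on population scales, N(mu, tau)
on individual weights. The default backend is penalized maximum a posteriori
(joint MAP over population and individual parameters, analytic gradients);
an optional MCMC backend samples the same posterior with emcee using a
non-centered parameterization of the random effects.

Model comparison follows the study's recipe: per-individual WAIC (standard
Watanabe definition, variance penalty), with pointwise log-likelihood draws
obtained from a Laplace approximation around each individual's mode, and
group-level random-effects Bayesian model selection summarized as the
protected exceedance probability (PXP) -- the posterior probability that each
model is the most frequent in the population, corrected by the Bayes omnibus
risk of the everyone-uses-the-same-chance-model null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from forageworld.choicemodel import ModelSpec, WeightVector
from forageworld.features import ChoiceRecord

N_LAPLACE_DRAWS = 200


# ---------------------------------------------------------------------------
# dense per-individual design (padded across variable candidate counts)


class _Design:
    """Padded tensors for fast vectorized likelihood/gradient of one individual."""

    def __init__(self, records: list[ChoiceRecord], spec: ModelSpec):
        if not records:
            raise ValueError("individual with zero modeled choices")
        self.feature_names = spec.resolve_features(records[0])
        self.dyn_features = list(spec.dynamic_map)
        self.dyn_pos = np.array(
            [self.feature_names.index(f) for f in self.dyn_features], dtype=int
        )
        P = len(self.feature_names)
        C = len(records)
        B = max(r.n_candidates for r in records)
        self.F = np.zeros((C, B, P))
        self.valid = np.zeros((C, B), dtype=bool)
        self.chosen = np.zeros(C, dtype=int)
        self.dtn = np.zeros((C, len(self.dyn_features)))
        for c, r in enumerate(records):
            if not (0 <= r.chosen < r.n_candidates):
                raise ValueError(f"chosen index outside candidate set at k={r.k}")
            self.F[c, : r.n_candidates] = r.matrix(self.feature_names)
            self.valid[c, : r.n_candidates] = True
            self.chosen[c] = r.chosen
            for j, f in enumerate(self.dyn_features):
                clock = spec.dynamic_map[f]
                self.dtn[c, j] = r.delta_t_norm.get(clock, 0.0)
        self.n_params = P + len(self.dyn_features)
        self.n_choices = C

    def _effective(self, theta: np.ndarray) -> np.ndarray:
        P = len(self.feature_names)
        w_eff = np.tile(theta[:P], (self.n_choices, 1))
        if len(self.dyn_pos):
            w_eff[:, self.dyn_pos] += self.dtn * theta[P:]
        return w_eff

    def _logits(self, theta: np.ndarray) -> np.ndarray:
        logits = np.einsum("cbp,cp->cb", self.F, self._effective(theta))
        return np.where(self.valid, logits, -np.inf)

    def loglik(self, theta: np.ndarray) -> float:
        logits = self._logits(theta)
        return float(
            (logits[np.arange(self.n_choices), self.chosen] - logsumexp(logits, axis=1)).sum()
        )

    def loglik_grad(self, theta: np.ndarray):
        logits = self._logits(theta)
        lse = logsumexp(logits, axis=1)
        ll = float((logits[np.arange(self.n_choices), self.chosen] - lse).sum())
        probs = np.exp(logits - lse[:, None])  # (C, B)
        G = (
            self.F[np.arange(self.n_choices), self.chosen]
            - np.einsum("cb,cbp->cp", probs, self.F)
        )  # (C, P)
        P = len(self.feature_names)
        grad = np.zeros(self.n_params)
        grad[:P] = G.sum(axis=0)
        if len(self.dyn_pos):
            grad[P:] = (G[:, self.dyn_pos] * self.dtn).sum(axis=0)
        return ll, grad

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        logits = self._logits(theta)
        return logits[np.arange(self.n_choices), self.chosen] - logsumexp(logits, axis=1)


# ---------------------------------------------------------------------------
# results containers


@dataclass
class FitResult:
    """Population and individual weight estimates with uncertainty and diagnostics."""

    spec_name: str
    parameter_names: list[str]
    population_mean: dict[str, float]
    population_sd: dict[str, float]
    interval: dict[str, tuple[float, float]]
    individual: dict[object, dict[str, float]]
    pointwise_loglik: dict[object, np.ndarray]  # draws x choices per individual
    converged: bool
    backend: str

    def to_dict(self) -> dict:
        return {
            "spec": self.spec_name,
            "backend": self.backend,
            "converged": self.converged,
            "population_mean": self.population_mean,
            "population_sd": self.population_sd,
            "interval": {k: list(v) for k, v in self.interval.items()},
            "individual": {str(k): v for k, v in self.individual.items()},
        }


@dataclass
class ModelComparison:
    """Per-individual WAICs, deltas to the best model, and PXP per model."""

    models: list[str]
    waic: dict[str, dict[object, float]]
    delta_waic: dict[str, float]
    pxp: dict[str, float]
    best_model: str

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "waic": {m: {str(i): v for i, v in d.items()} for m, d in self.waic.items()},
            "delta_waic": self.delta_waic,
            "pxp": self.pxp,
            "best_model": self.best_model,
        }


# ---------------------------------------------------------------------------
# MAP fitting


def _fit_single(design: _Design, seed: int = 0):
    """MAP of one individual under the flat population prior N(0, 1)."""

    def obj(theta):
        ll, g = design.loglik_grad(theta)
        return -(ll - 0.5 * float(theta @ theta)), -(g - theta)

    res = minimize(obj, np.zeros(design.n_params), jac=True, method="L-BFGS-B")
    return res.x, bool(res.success)


def _numeric_hessian(grad_fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        dx = np.zeros(n)
        dx[i] = eps
        H[:, i] = (grad_fn(x + dx) - grad_fn(x - dx)) / (2 * eps)
    return 0.5 * (H + H.T)


def _laplace_draws(design: _Design, theta_hat: np.ndarray, n_draws: int, seed: int):
    """Pointwise log-likelihood draws from the Laplace approximation of one
    individual's posterior (flat N(0,1) pooling)."""

    def neg_grad(theta):
        _, g = design.loglik_grad(theta)
        return -(g - theta)

    H = _numeric_hessian(neg_grad, theta_hat)
    # guard: force positive definiteness
    w, V = np.linalg.eigh(H)
    w = np.clip(w, 1e-8, None)
    cov_sqrt = V @ np.diag(1.0 / np.sqrt(w))
    rng = np.random.default_rng(seed)
    draws = theta_hat[None, :] + rng.standard_normal((n_draws, len(theta_hat))) @ cov_sqrt.T
    return np.stack([design.pointwise_loglik(th) for th in draws])


def _random_effects_map(theta_hat: np.ndarray, s2: np.ndarray) -> tuple[float, float, float]:
    """MAP of (mu, tau) for one parameter across individuals.

    Model: theta_hat_i ~ N(mu, tau^2 + s2_i) with mu ~ N(0, 1) and
    tau ~ Exponential(1); the individual-level uncertainty s2_i comes from the
    Laplace approximation of that individual's likelihood. Returns
    (mu, tau, sd(mu)).
    """

    def obj(x):
        mu, lt = x
        tau2 = np.exp(2 * lt)
        v = tau2 + s2
        return (
            0.5 * float(np.sum(np.log(v) + (theta_hat - mu) ** 2 / v))
            + 0.5 * mu**2
            + np.exp(lt)
            - lt
        )

    best = None
    for lt0 in (-3.0, 0.0):
        res = minimize(obj, np.array([theta_hat.mean(), lt0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mu, lt = best.x
    tau2 = np.exp(2 * lt)
    # curvature of the profile in mu gives the population-mean uncertainty
    prec = float(np.sum(1.0 / (tau2 + s2)) + 1.0)
    return float(mu), float(np.exp(lt)), float(1.0 / np.sqrt(prec))


def _unpack(x: np.ndarray, P: int, N: int):
    mu = x[:P]
    log_tau = x[P : 2 * P]
    eta = x[2 * P :].reshape(N, P)
    return mu, log_tau, eta


def _hier_obj(x: np.ndarray, designs: list[_Design]):
    """Negative log joint posterior (and gradient) of the partial-pooling model.

    Parameterized non-centered (theta_i = mu + tau * eta_i, eta ~ N(0,1)):
    the centered joint density is unbounded as tau -> 0 (the usual funnel
    degeneracy), whereas the non-centered mode is well-defined.
    """
    N = len(designs)
    P = designs[0].n_params
    mu, log_tau, eta = _unpack(x, P, N)
    tau = np.exp(log_tau)
    theta = mu[None, :] + tau[None, :] * eta
    nll = 0.0
    grad_theta = np.zeros((N, P))
    for i, d in enumerate(designs):
        ll, g = d.loglik_grad(theta[i])
        nll -= ll
        grad_theta[i] = -g
    val = (
        nll
        + 0.5 * float((eta**2).sum())
        + 0.5 * float(mu @ mu)
        + float(tau.sum())  # Exponential(1) prior on tau
        - float(log_tau.sum())  # Jacobian of the log transform
    )
    grad_mu = grad_theta.sum(axis=0) + mu
    grad_eta = grad_theta * tau[None, :] + eta
    grad_log_tau = (grad_theta * eta).sum(axis=0) * tau + tau - 1.0
    return val, np.concatenate([grad_mu, grad_log_tau, grad_eta.ravel()])


def fit_model(
    data: dict[object, list[ChoiceRecord]],
    spec: ModelSpec,
    backend: str = "map",
    seed: int = 0,
    n_draws: int = N_LAPLACE_DRAWS,
    mcmc_steps: int = 1500,
    mcmc_burn: int = 500,
) -> FitResult:
    """Fit a choice model to per-individual choice records.

    With a single individual the population prior degenerates to N(0, 1) on the
    weights; with several, individuals are partially pooled toward population
    means. ``backend='mcmc'`` samples the same hierarchical posterior with
    emcee (non-centered random effects) instead of optimizing it.
    """
    individuals = list(data.keys())
    if not individuals:
        raise ValueError("no individuals to fit")
    designs = [_Design(data[i], spec) for i in individuals]
    P = designs[0].n_params
    names = spec.parameter_names(data[individuals[0]][0])
    if backend == "mcmc":
        return _fit_mcmc(data, spec, designs, individuals, names, seed, mcmc_steps, mcmc_burn, n_draws)
    if backend != "map":
        raise ValueError(f"unknown backend {backend!r}")

    if len(individuals) == 1:
        theta, ok = _fit_single(designs[0], seed)

        def neg_grad(th):
            _, g = designs[0].loglik_grad(th)
            return -(g - th)

        H = _numeric_hessian(neg_grad, theta)
        cov = np.linalg.inv(H + 1e-10 * np.eye(P))
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        pw = {individuals[0]: _laplace_draws(designs[0], theta, n_draws, seed)}
        return FitResult(
            spec_name=spec.name,
            parameter_names=names,
            population_mean=dict(zip(names, theta)),
            population_sd={n: 0.0 for n in names},
            interval={n: (t - 1.96 * s, t + 1.96 * s) for n, t, s in zip(names, theta, sd)},
            individual={individuals[0]: dict(zip(names, theta))},
            pointwise_loglik=pw,
            converged=ok,
            backend="map",
        )

    N = len(individuals)
    # Laplace-approximate each individual's likelihood, then pool by
    # random-effects meta-analysis per parameter under the stated priors.
    # (The joint hierarchical mode is parameterization-dependent and the
    # centered version is a funnel; the marginalized form is well-behaved.)
    theta_hat = np.zeros((N, P))
    s2 = np.zeros((N, P))
    ok = True
    for i, d in enumerate(designs):
        th, success = _fit_single(d, seed)
        ok = ok and success

        def neg_grad(x, d=d):
            _, g = d.loglik_grad(x)
            return -(g - x)

        H = _numeric_hessian(neg_grad, th)
        H_lik = H - np.eye(P)  # remove the flat N(0,1) fitting prior
        w_eig, V = np.linalg.eigh(H_lik)
        w_eig = np.clip(w_eig, 1e-6, None)
        cov = V @ np.diag(1.0 / w_eig) @ V.T
        theta_hat[i] = th
        s2[i] = np.clip(np.diag(cov), 1e-8, 1e6)

    mu = np.zeros(P)
    tau = np.zeros(P)
    mu_sd = np.zeros(P)
    for p in range(P):
        mu[p], tau[p], mu_sd[p] = _random_effects_map(theta_hat[:, p], s2[:, p])
    # posterior-mean shrinkage of individual estimates toward the population mean
    with np.errstate(divide="ignore"):
        prec_tau = np.where(tau > 1e-8, 1.0 / tau**2, np.inf)
    theta = np.where(
        np.isinf(prec_tau)[None, :],
        np.tile(mu, (N, 1)),
        (theta_hat / s2 + mu[None, :] * prec_tau[None, :]) / (1.0 / s2 + prec_tau[None, :]),
    )
    log_tau = np.log(np.clip(tau, 1e-12, None))

    pw = {
        ind: _laplace_draws(d, theta[i], n_draws, seed + 1 + i)
        for i, (ind, d) in enumerate(zip(individuals, designs))
    }
    return FitResult(
        spec_name=spec.name,
        parameter_names=names,
        population_mean=dict(zip(names, mu)),
        population_sd=dict(zip(names, np.exp(log_tau))),
        interval={n: (m - 1.96 * s, m + 1.96 * s) for n, m, s in zip(names, mu, mu_sd)},
        individual={ind: dict(zip(names, theta[i])) for i, ind in enumerate(individuals)},
        pointwise_loglik=pw,
        converged=ok,
        backend="map",
    )


def _fit_mcmc(data, spec, designs, individuals, names, seed, steps, burn, n_draws):
    """Ensemble-sampler backend: non-centered random effects theta = mu + tau * eta."""
    import emcee

    N = len(individuals)
    P = designs[0].n_params

    def log_prob(x):
        mu = x[:P]
        log_tau = x[P : 2 * P]
        eta = x[2 * P :].reshape(N, P)
        tau = np.exp(log_tau)
        if np.any(log_tau > 4) or np.any(np.abs(x) > 60):
            return -np.inf
        theta = mu[None, :] + tau[None, :] * eta
        ll = sum(d.loglik(theta[i]) for i, d in enumerate(designs))
        lp = (
            -0.5 * float((eta**2).sum())
            - 0.5 * float(mu @ mu)
            - float(tau.sum())
            + float(log_tau.sum())
        )
        return ll + lp

    ndim = 2 * P + N * P
    nwalkers = 2 * ndim + 2
    rng = np.random.default_rng(seed)
    # initialize the ensemble around the joint MAP (non-centered coordinates)
    x_init = np.zeros(ndim)
    x_init[P : 2 * P] = np.log(0.5)
    res = minimize(_hier_obj, x_init, args=(designs,), jac=True, method="L-BFGS-B")
    x0 = res.x[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(x0, steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=burn, flat=True)
    mu_draws = chain[:, :P]
    tau_draws = np.exp(chain[:, P : 2 * P])
    theta_draws = chain[:, 2 * P :].reshape(len(chain), N, P)
    theta_draws = mu_draws[:, None, :] + tau_draws[:, None, :] * theta_draws
    qs = np.quantile(mu_draws, [0.025, 0.975], axis=0)
    sub = np.linspace(0, len(chain) - 1, min(n_draws, len(chain))).astype(int)
    pw = {
        ind: np.stack([d.pointwise_loglik(theta_draws[s, i]) for s in sub])
        for i, (ind, d) in enumerate(zip(individuals, designs))
    }
    return FitResult(
        spec_name=spec.name,
        parameter_names=names,
        population_mean=dict(zip(names, mu_draws.mean(axis=0))),
        population_sd=dict(zip(names, tau_draws.mean(axis=0))),
        interval={n: (qs[0, j], qs[1, j]) for j, n in enumerate(names)},
        individual={
            ind: dict(zip(names, theta_draws[:, i, :].mean(axis=0)))
            for i, ind in enumerate(individuals)
        },
        pointwise_loglik=pw,
        converged=True,
        backend="mcmc",
    )


# ---------------------------------------------------------------------------
# WAIC and protected exceedance probability


def waic(pointwise_loglik: np.ndarray) -> float:
    """Widely applicable information criterion, -2 (lppd - p_waic).

    ``pointwise_loglik`` has one row per posterior draw and one column per
    choice; the penalty is the summed posterior variance of the pointwise
    log-likelihoods.
    """
    pw = np.asarray(pointwise_loglik, dtype=float)
    if pw.ndim != 2 or pw.shape[0] < 2:
        raise ValueError("waic requires a draws x observations matrix with >= 2 draws")
    lppd = float(logsumexp(pw, axis=0).sum() - pw.shape[1] * np.log(pw.shape[0]))
    p_waic = float(pw.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic)


def exceedance_probability(alpha: np.ndarray, n_samples: int = 100_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior."""
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    counts = np.bincount(np.argmax(draws, axis=1), minlength=len(alpha))
    return counts / n_samples


def protected_exceedance_probability(
    log_evidence: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> np.ndarray:
    """Random-effects Bayesian model selection with the null-model correction.

    ``log_evidence`` is a (models x individuals) matrix of per-individual log
    model evidences. A variational Dirichlet scheme estimates the population
    frequencies of model use; exceedance probabilities are corrected by the
    Bayes omnibus risk (the posterior probability that differences arose by
    chance), yielding PXP = EP * (1 - BOR) + BOR / K. Returns probabilities
    summing to 1.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2:
        raise ValueError("need a (models x individuals) matrix with >= 2 models")
    K, N = lme.shape
    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    u = np.full((N, K), 1.0 / K)
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        log_u = lme.T + e_log_r[None, :]
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    ep = exceedance_probability(alpha, n_samples=n_samples, seed=seed)

    # free energy of the random-effects model
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    log_u = np.log(np.clip(u, 1e-300, None))
    ln_beta = lambda a: float(gammaln(a).sum() - gammaln(a.sum()))
    F1 = (
        float((u * (lme.T + e_log_r[None, :] - log_u)).sum())
        + float(((alpha0 - alpha) * e_log_r).sum())
        + ln_beta(alpha)
        - ln_beta(alpha0)
    )
    # null model: every individual uses the same chance distribution over models
    F0 = float(logsumexp(lme - np.log(K), axis=0).sum())
    bor = 1.0 / (1.0 + np.exp(np.clip(F1 - F0, -700, 700)))
    pxp = ep * (1.0 - bor) + bor / K
    return pxp / pxp.sum()


def compare_models(
    data: dict[object, list[ChoiceRecord]],
    specs: list[ModelSpec],
    seed: int = 0,
    n_draws: int = N_LAPLACE_DRAWS,
) -> ModelComparison:
    """Per-individual WAIC for each model and group-level PXP.

    Each individual is fitted independently (N(0,1) priors) per model; the
    per-individual log evidence entering the random-effects selection is
    -WAIC/2.
    """
    if len(specs) < 2:
        raise ValueError("model comparison requires at least two models")
    individuals = list(data.keys())
    waics = {s.name: {} for s in specs}
    for m, spec in enumerate(specs):
        for i, ind in enumerate(individuals):
            design = _Design(data[ind], spec)
            theta, _ = _fit_single(design)
            pw = _laplace_draws(design, theta, n_draws, seed + 1000 * m + i)
            waics[spec.name][ind] = waic(pw)
    lme = np.array(
        [[-0.5 * waics[s.name][ind] for ind in individuals] for s in specs]
    )
    pxp = protected_exceedance_probability(lme, seed=seed)
    totals = {s.name: sum(waics[s.name].values()) for s in specs}
    best = min(totals, key=totals.get)
    delta = {m: totals[m] - totals[best] for m in totals}
    return ModelComparison(
        models=[s.name for s in specs],
        waic=waics,
        delta_waic=delta,
        pxp={s.name: float(pxp[i]) for i, s in enumerate(specs)},
        best_model=best,
    )
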