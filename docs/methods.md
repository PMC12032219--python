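# Methods

`forageworld` implements the computational stack of a collective spatial-foraging
task: four players forage for 120 s on a 20 x 20 field of destructible blocks, 25%
of which hide a binary reward, either scattered uniformly ("random") or spatially
clustered ("smooth"). Players see only a 108.5-degree horizontal field of view, so
attention is split between individual search and watching peers; a rewarded
destruction produces a splash visible to any observer whose FOV contains it. This
note documents the models, the numerical choices, and what the synthetic data can
and cannot show.

## Reward environments (`envgen`)

Smooth fields are drawn from a zero-mean Gaussian process with RBF kernel
`k(x, x') = exp(-||x - x'||^2 / 2 l^2)` on grid coordinates (default lengthscale
`l = 4` grid units, jitter 1e-8 on the kernel diagonal) and binarized at the 75th
percentile, so exactly 100 of 400 cells are rewarded; random fields draw the 100
cells uniformly without replacement. Binarization is rank-based with row-major
tie-breaking, so the count is exact for every seed. Grid-to-world mapping is a
single spacing constant (3.0 world units center-to-center). The generating
lengthscale (grid units) and the cognitive-model lengthscale (sqrt(48) world
units) are kept as two separate constants: the task descriptions relating them
(two empty blocks between neighbors, a sqrt(3) scaling factor, one empty tile per
side) are mutually inconsistent, so neither is derived from the other.

## GP binary reward prediction (`gpclass`)

A forager's belief is GP binary classification over block locations:
`p(r=1|z) = S(z)` with logistic `S`, prior mean `z0 = log(.25/.75)` (so the prior
predictive is exactly the 25% base rate), noise variance 1e-4, and the RBF kernel
at `l = sqrt(48)` world units. The algebra is carried out in centered latent space
(`z - z0`); the prior mean is added back after the probit variance moderation:

    p(r=1 | D) ~= S( z0 + mu_* (1 + pi sigma_*^2 / 8)^(-1/2) )

with `mu_* = k_*^T (r - S(z_hat + z0))` and
`sigma_*^2 = k(x_*,x_*) - k_*^T (W^{-1} + K + sigma^2 I)^{-1} k_*`.

The posterior mode is found by the standard Newton/IRLS update
`z_new = K_z (I + W K_z)^{-1} (W z + r - S(z + z0))`, tolerance 1e-6 on the mode,
at most 100 iterations (non-convergence raises an explicit error). An
alternative fixed-point form that omits `W` from the matrix inverse was
evaluated and rejected: its fixed point is not the posterior mode, and its predictive
probabilities deviate from an exact-moments quadrature reference by up to 0.014,
versus under 0.005 for Newton.

Two accuracy caveats are inherent to the approximation and bounded by tests:
the probit moderation itself differs from the fully exact Bayesian predictive by
up to ~0.04 at prior-dominated inputs (the quadrature oracle therefore isolates
the Laplace step: exact latent moments, same squash), and monotonicity in a
flipped observation holds only to ~1e-3.

## Choice features (`features`)

Choice `k+1` is predicted from the state of the world at destruction `k`
(modeling starts at the second destruction). Asocial features: locality (inverse
distance from the player to each candidate, floored at 1 block to bound the
weight), block visibility (inclusive geometric FOV test on the horizontal heading,
no occlusion, unlimited range), and the GP predictive probability from the
player's own history (a config switch substitutes the latent mean). Social
features: inverse distance from candidates to the last observed location of peers
visible during `(t_{k-1}, t_k]`, split into successful (observed splash in the
interval) vs. unsuccessful, with the centroid used for multiple qualifying peers
and an all-zero column when none qualify; a player-specific variant yields one
column per peer. All non-binary columns are z-standardized within each choice;
zero-variance columns become all-zeros rather than NaN. The distance floor of
1 block is used uniformly (locality, social proximity, network edges).

## Choice models (`choicemodel`)

`P(choice) ∝ exp(f . w)` over the remaining blocks. Dynamic models replace
selected weights with `w + alpha * dt_norm`, where `dt` is the elapsed time since
the last event on the feature's clock — own reward (`individual_reward`) or
observed splash (`social_observed_reward`), initialized at round start — and
`dt_norm` is z-standardized across all choices in the fitted dataset so `alpha`
is on the scale of the static weights. Registry: Asocial, Unbiased (+ social
proximity), SuccessBiased (+ successful/unsuccessful proximity), PlayerSpecific,
ARS (locality on the individual clock), Critical (reward prediction on the social
clock; the social clock does not reset on own rewards), Conditional (both
proximity weights on the individual clock), ARSCond (ARS + Conditional).
`synthesize_records` generates standalone standardized feature sets with the same
column structure for recovery simulations.

## Fitting and model selection (`fitting`)

Default backend: per-individual penalized MAP (standard normal prior) with
analytic gradients, then partial pooling by per-parameter random-effects
meta-analysis — each individual's likelihood is Laplace-approximated as
`N(theta_hat_i, s_i^2)` and `(mu, tau)` maximize the marginal posterior under
`mu ~ N(0,1)`, `tau ~ Exponential(1)`. A joint hierarchical mode was rejected:
the centered parameterization is an unbounded funnel at `tau -> 0`, and the
non-centered joint mode splits individual effects between `mu` and `tau*eta`,
biasing the population mean. The optional MCMC backend samples the same posterior
with an emcee ensemble sampler (non-centered random effects, walkers initialized
at the joint optimum); with several individuals the two backends agree on
population means within 0.1, while with very few the full posterior is
prior-dominated at the population level and legitimately shrinks harder.

WAIC uses the standard definition `-2(lppd - p_waic)` with the variance penalty,
on 200 pointwise log-likelihood draws from the per-individual Laplace
approximation (numeric Hessian of the penalized objective, eigenvalue-clipped).
Group-level selection is random-effects Bayesian model selection: a variational
Dirichlet scheme over per-individual log evidences (`-WAIC/2`), Monte-Carlo
exceedance probabilities, and the Bayes-omnibus-risk correction
`PXP = EP (1 - BOR) + BOR / K`, where `BOR = 1/(1 + exp(F1 - F0))` compares the
free energy of the random-effects model against the all-models-equal null.

## Agent-based simulation (`agentsim`)

A discrete-time sequential game at 0.25 s per step, horizon 400 steps: each agent
cycles SelectDest (softmax over available blocks, all feature weights 1) ->
NavTo (greedy cardinal steps, ties broken N,E,S,W) -> forage (9 steps = 2.25 s;
first completer is credited). Agents move one block (1 world unit) per step,
i.e. 4 blocks/s, matching the task's 4.3 blocks/s maximum speed; heading is the
last movement direction. Reveal events (splashes) broadcast once, at the
destruction step, to agents whose FOV contains the block. Asocial agents use
locality + visibility + own-history GP prediction; unbiased social agents add
mean inverse distance to partners observed since their last choice; biased social
agents restrict that to partners observed acquiring a reward. GP beliefs update
on own destructions only.

The full study-scale design (20 envs x 2 types x 100 replicates x 3 strategies =
12,000 runs) is enumerable without execution; tests execute a scaled design
(5 x 2 x 20 x 3, 400 steps). Under it, unbiased imitation is clearly worst in
both environment types and success-biased learning has no advantage in random
fields; the remaining expectation — that success-biased learning should beat
asocial search in smooth fields, which motivates the agent types — does not
materialize: biased and asocial agents are statistically indistinguishable in
smooth fields. With GP generalization and locality-dominated search, asocial
groups already achieve a ~63% hit rate in smooth fields, leaving no headroom for
social targeting to raise group efficiency; this limitation is deliberate, not
tuned away, and the corresponding ordinal check is expected to fail in part.

## Pull events (`pulls`)

Dyadic distance series at 20 Hz are reduced to alternating extrema with a 1-block
noise threshold applied to both excursions (plateaus take their first index;
consecutive candidates share endpoints). Candidate (min, max, min) triples become
pulls when strength > 0.1, disparity > 0.1 (segment displacements are net
Euclidean), duration >= 3 s, and the leader (moved more in the first segment)
differs from the follower. Candidates with a zero-movement segment have undefined
disparity and are dropped. Dyads are evaluated independently.

## Temporal dynamics (`tempdyn`)

Pearson correlations of two 20 Hz series at offsets -20..+20 s (native 0.05-s
step by default; tests use a 1-s stride for speed), Fisher-z transformed with
|r| clipped at 1 - 1e-6, computed on the overlapping region only; constant
windows are recorded as missing. Chance correction subtracts the mean z over 100
order-permutations of the second series — an estimate of the chance level, which
is near zero for exchangeable series. Cluster testing: per-offset two-sided
one-sample t-tests (alpha = 0.05) across individual corrected series; contiguous
same-sign significant runs form clusters; a sign-flip null (each value's sign
flipped independently per time point, which breaks across-offset
autocorrelation) yields the max-cluster-duration distribution, and
observed clusters survive only if their duration strictly exceeds the null's 95th
percentile. Strict exceedance is essential with integer-valued durations:
keeping clusters at the threshold inflates the family-wise error severalfold.

## Networks (`networks`)

Proximity networks: undirected, mean inverse pairwise distance per round (floored
at 1 block). Visibility networks: directed observer->target edges weighted by
raw seconds of visibility (normalization left to the caller). Eigenvector
centrality on proximity networks uses the principal eigenvector
(per-component on disconnected graphs, with a warning), normalized to unit
maximum. A helper averages networks across rounds per condition.

## Synthetic sessions (`session`)

Logs follow a tidy schema at the native 20 Hz tick (player log: time, player, XZ,
heading; map log: destruction events; visibility log: visible peers and splashes
per tick, derived geometrically at write time so downstream modules never
re-derive it inconsistently). Splashes stay observable for 1.0 s (configurable;
the real duration and occlusion effects are unknown). Generators: `agentsim`
renders simulator episodes (0.25-s states upsampled linearly to 20 Hz),
`random_walk` produces momentum random walks with reward-independent destruction
schedules (per-player gaps of 2.25 s plus an exponential with mean 1.5 s, nearest
available block destroyed), `scripted` replays waypoint scripts for exact
fixtures. Solo sessions put four players on independent replicate fields (empty
visibility log); `solo_superposition` merges them with shared block removal and
one splash per reward event. What the generators do not emulate: human-like
heading dynamics (scanning), speed limits in the random-walk mode, occlusion,
or adaptive behavior in the null modes — so passing tests demonstrate the
correctness and calibration of the analyses, not behavioral realism.

## Problem sizes used in tests

Environment comparisons use 300-1,000 draws; GP oracle checks 25-40 random
1-3-observation configurations; parameter recovery 3,000 choices; model recovery
16 synthetic individuals x 150 choices across all eight models; the simulation
design 5 envs x 2 types x 20 replicates x 3 strategies at 400 steps; cluster-test
calibration 1,000 white-noise replicates at 500 permutations and power 200
replicates of a planted 5-s, r = 0.5 dependence (16 series of 2,400 ticks,
20 chance-correction permutations).
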