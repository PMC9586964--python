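# Methods

This note documents the models, the synthetic-data generator, the
fitting and model-selection machinery, and the numerical and design
choices behind them. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external sources.

## The task

The two-step task is a sequential decision paradigm. Each trial starts
in a single initial state `s_A` with two actions. Action `a_A` moves
the agent to final state `s_B` with probability 0.7 (common transition)
and to `s_C` with probability 0.3 (rare); `a_B` has the mirrored
mapping. Each final state offers two actions; choosing one yields a
binary outcome `o ∈ {0, 1}`, with `o = 1` coding the preferred event
(reward delivered, or shock absent in aversive variants). The four
outcome probabilities drift as independent Gaussian random walks with
reflecting boundaries — increment s.d. 0.025 inside [0.25, 0.75] for
reward paradigms, 0.2 inside [0, 1] for the aversive variant. The
reflection rule is the standard mirror construction `v' = 2·bound − v`,
iterated until the value is inside the interval; it preserves the
walk's symmetry and never leaves the bounds (checked over 10^5 steps in
the tests).

Generator choices left open by the design and fixed here:

- **Walk initialisation.** Each walk starts uniform within its bounds
  (configurable to the midpoint). Uniform initialisation matches the
  walk's stationary tendency to spread over the interval.
- **Trials per session.** Default 201, a typical session length for
  this task family; configurable.
- **Encodings.** Actions `a_A = 0, a_B = 1`; states `s_A = 0, s_B = 1,
  s_C = 2` everywhere, including the CSV trial schema.
- **Outcome valence.** The canonical schema always stores `o = 1` as
  the preferred event, so one model codebase serves reward and shock
  paradigms alike.

What the generator does *not* emulate: reaction times, missed or
invalid trials, stimulus graphics, instruction manipulations, and any
within-session nonstationarity of participants (fatigue, attention).
Tests passing on this generator therefore validate the algorithms and
their implementations, not claims about any particular human dataset.

## Transition learning (shared by both model families)

Agents count observed (initial action → final state) transitions and on
every trial adopt the more likely of the two mirrored candidate
structures by product-Bernoulli likelihood; the flat 0.5 structure is
held only while the evidence is exactly tied (in particular, before any
observations). Participants are trained to know the structure is one of
the two mirrored options, so flat probabilities represent ignorance
rather than a live hypothesis; scoring flat as a third likelihood
candidate would have it win whenever more than ~40% of observed
transitions were rare, which keeps the correct structure from being
identified reliably within the first block of trials. With the
tie-only rule the correct structure is identified with probability
≈ 0.95 after 20 trials (`P(Binom(20, 0.7) ≥ 11)`), verified by
simulation in the tests.

## Hybrid reinforcement-learning agent

Model-free values follow SARSA(λ) over the two stages. At outcome time
the prediction errors are

    δ1 = Q(s2, a2) − Q(s_A, a1)        (no outcome at stage 1)
    δ2 = o − Q(s2, a2)

and the visited pairs update as

    Q(s_A, a1) += α1·δ1 + α1·λe·δ2
    Q(s2, a2)  += α2·δ2

with stage learning rates `α1, α2` and eligibility `λe` passing the
final-stage error back to the initial-stage pair. Model-based
initial-stage values plan through the inferred structure:
`Q_MB(a) = p(s_B|a)·max Q(s_B,·) + p(s_C|a)·max Q(s_C,·)`. The net
initial-stage value is the convex mixture `w·Q_MB + (1−w)·Q_MF`; the
final stage needs no mixture because the strategies coincide there.
Choice is softmax with stage inverse temperatures `β1, β2` and a
stickiness bonus `ρ` for repeating the previous initial choice
(stage 1 only, no bonus on trial 1).

Choices fixed here: Q-values initialise at zero; unvisited pairs never
decay; the session likelihood is the product of stage-1 and stage-2
choice probabilities per trial. `w = 0` and `w = 1` reduce exactly to
the pure model-free and pure model-based agents (asserted as exact
log-likelihood equalities in the tests).

## Active-inference agent

The agent holds independent Beta(α, β) beliefs over the four
final-stage outcome probabilities. The prior has mean `prior_mean`
(a free parameter) and total concentration fixed at 2 — a
unit-information prior; only the mean is fitted because mean and scale
are not separately identifiable from a binary outcome stream of this
length.

**Action selection.** Each final-stage action is scored by expected
free energy

    G(a) = −E_q[ln p(o|C)] − E_q[ KL( posterior-after-o ‖ current ) ]

where `q(o=1) = α/(α+β)` is the predictive distribution, `p(o|C)` is a
Bernoulli preference kernel with precision λ (at λ = 0 both outcomes
are equally preferred and the agent is a pure information seeker), and
the KL term is the expected information gain. The hypothetical
posterior inside the KL is the one-step conjugate update with unit
increment — not the learning-rate-scaled, decayed update — so that the
exploration incentive is independent of the learning kinetics; a flag
switches to the `l`-scaled increment. Initial-stage EFE propagates
through the inferred transition structure as transition-probability-
weighted *sums* of the two final-stage EFEs per state. Summing (rather
than averaging or policy-weighting) the final-stage EFEs is kept as the
model's definition; it only rescales the initial-stage EFE differences
when final-stage values are similar. Choice is
`softmax(−γp·G + E_a)` with stage precisions `γ1, γ2`; `E_a` is a
static Bernoulli habit kernel with precision κ favouring a repeat of
the previous initial choice (zero on trial 1 and at the final stage;
at κ = 0 it shifts both logits equally and has no effect).

**Belief updating.** The Beta KL divergence is closed-form via log-Beta
and digamma functions and is validated against numerical quadrature to
1e−6 over 1000 random parameter draws. Four learning variants share one
update rule:

1. *Sampled pair*: predictive surprise `PS = −ln p(o)` is mapped to an
   adaptation rate `χ = mS/(1+mS)`, `m = ν_PS/(1−ν_PS)`; concentrations
   shrink by `(1−χ)` and the observed outcome adds `l` to the matching
   concentration. The shrinkage is implemented without a compensating
   `+χ·prior` pull (a flag restores it); the 1e−6 floor on
   concentrations guarantees stability.
2. *Sampled pair, static decay*: concentrations then decay toward the
   prior at rate `ν_SD` (surprise step first, then decay).
3. *Unsampled pairs*: concentrations decay toward the prior at rate
   `ν_UD`, modelling gradual loss of confidence about unexplored
   options.

The Full variant fits all three volatilities; NPS, NSD and NUD pin
`ν_PS`, `ν_SD` or `ν_UD` to zero respectively. With all volatilities
zero and `l = 1` the update is exactly conjugate Beta-Bernoulli
counting (asserted trial-by-trial in the tests). One convention is
worth flagging: the predictive probability of `o = 1` is `α/(α+β)`
everywhere, consistent with α accumulating observed 1s.

## Maximum-likelihood fitting

The likelihood replays a session: on each trial the model's
probabilities for the subject's actual two choices are computed with
all internal state (values, beliefs, transition counts, habit)
conditioned on the subject's actual history, and their logs
accumulated. Choice probabilities are floored at 1e−12. Optimisation is
bounded L-BFGS-B (numerical gradients, gradient tolerance 1e−6) from 25
uniform-random starts within bounds; the best restart wins. Bounds:
learning rates, eligibility, `w` and volatilities in [0, 1] (volatility
upper bound 0.999 to keep `m = ν/(1−ν)` finite); inverse temperatures
in [0, 20]; stickiness and habit precision in [−5, 5]; λ in [0, 10];
prior mean in [0.05, 0.95]; `l` in [0.01, 2]. Free-parameter counts:
hybrid 7, active-inference Full 9, each ablated variant 8. AIC and BIC
are the standard `2k − 2lnL̂` and `k·ln n − 2lnL̂`.

The replay loop is compiled with numba (`_kernels.py`); the pure-Python
agent classes implement the identical algorithm and the tests assert
agreement to 1e−9, so the compiled path never drifts from the readable
one.

## Trial-history regression

Initial-stage choices are regressed on the previous four trials'
choices `x`, outcomes `o`, transitions `τ` (all ±1) and the `o·τ`
interaction, giving 16 regressors (4 lags × 4 families) and no global
intercept — the lagged-choice terms absorb choice autocorrelation. The
first four trials are dropped (incomplete history). The fit is
L2-penalised logistic regression at unit inverse penalty strength
(scikit-learn's default), which also guarantees finite coefficients
under perfect separation; an unpenalised option exists. A model-free
learner loads on the outcome main effect; a model-based learner on the
outcome × transition interaction — this dissociation is asserted over
simulated cohorts in the acceptance tests.

## Model selection

Per-subject log model evidence is approximated by −AIC/2 or −BIC/2.
Group inference is random-effects: model identity is a subject-level
random effect with Dirichlet-distributed population frequencies,
estimated by the standard variational scheme (subject posteriors
`∝ exp(evidence + ψ(α_k) − ψ(Σα))`, concentrations `α = α0 + Σ
posteriors`, iterated to `|Δα| < 1e−6`). Exceedance probabilities are
Monte-Carlo estimates from 10^6 Dirichlet draws (the two-model case is
cross-checked against the closed-form Beta tail in the tests).
Protected exceedance probabilities blend exceedance with uniform
according to the Bayesian omnibus risk, computed as the posterior
probability of the equal-frequency null from the free energy of the
alternative (variational bound) against the exact null evidence
`Σ_n [logsumexp(evidence_n) − ln K]`, at equal prior odds.

Family-level inference uses F-unity priors — one unit of prior mass per
family, split evenly over members — but samples the exact posterior by
Gibbs (alternating frequency draws and subject assignments) instead of
the variational scheme. The reason is a genuine failure mode: under
non-uniform priors the variational updates weight each model by
`exp(ψ(α_k))` and break the symmetry of identical evidences toward the
family with fewer members, whereas the exact posterior reduces to the
prior in that case. The Gibbs sampler (20,000 samples after 2,000
burn-in) reproduces the correct symmetric answer and matches the
variational result when priors are uniform.

One scale caveat, measured in the tests: the omnibus risk under an
*exact* null grows toward 1 only as subjects × models grow (0.90 at
20 subjects × 3 models, 0.99 at 40 × 5), because it is driven by the
variational free-energy gap. Null-behaviour checks therefore use the
package's natural model space (five models) at cohort size 40.

## Recovery and group analyses

Posterior-predictive analyses simulate each fitted subject 20 times
from their maximum-likelihood parameters (fresh walks each run, seeds
derived deterministically from a master seed) and average regression
coefficients across runs. Parameter recovery refits synthetic sessions
with the same 25-restart procedure and reports, per parameter,
Spearman rank correlation on raw values and Pearson correlation on
offset-log-transformed values (each variable offset so its minimum is
1, then logged — the usual treatment for skewed, bounded estimates).
Subjects are stratified into low/high preference-precision groups at
λ = 1.5 (the boundary value goes to the high group); per-subject mean
obtained reward is compared with Welch's t-test, reporting
`100·(high − low)/low` percent difference.

**A documented limitation.** λ recovery is strong at low λ and
compressed above λ ≈ 3: the preference term `2λΔq` saturates the choice
sigmoid, and profile analysis shows log-likelihood differences of only
1–2 nats between λ = 5 and λ = 10 over 201 trials. In the joint
9-parameter fit the MLE can genuinely sit at a different λ with
compensating prior mean / precision / volatility values (the refits
beat the true parameters' likelihood in every inspected case). A
synthetic cohort with λ uniform on [0, 10] therefore yields a rank
correlation near 0.5, dominated by the compressed upper region; rank
recovery is much better on cohorts concentrated at low λ or split
between the extremes. The acceptance suite documents this honestly:
its λ-recovery check is expected to fall short of its 0.6 bar under
the uniform design.

The λ-recovery cohort fixes nuisance parameters at a behaviourally
functional operating point — γ1 = γ2 = 5, κ = 0, prior mean 0.5,
l = 1, all volatilities 0.1. Volatilities near 0.5 would pin beliefs at
the prior (per-trial decay plus surprise shrinkage outpace the unit
evidence increment), flattening the extrinsic-value gradient that λ
scales and making λ behaviourally inert; mild forgetting keeps beliefs
informative while retaining all three kinetics.

## Problem sizes

Defaults chosen for the bundled analyses: cohorts of 8–30 subjects at
201 trials; 100 subjects per arm for the regression dissociation; 20
replicate cohorts of 40 subjects for model-recovery checks; 10^5-step
walk-invariant checks; 10^6 Dirichlet draws for exceedance (10^5 in
replicated loops). These sizes give stable estimates for every
qualitative effect while keeping any single analysis in the minutes
range on one CPU.
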