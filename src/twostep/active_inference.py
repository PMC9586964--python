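"""Active-inference agent with Beta-Bernoulli outcome beliefs.

The agent holds a Beta distribution over each final-stage (state,
action) outcome probability and selects actions by minimising expected
free energy (EFE), which decomposes into an extrinsic value (expected
log preference probability of the outcome) and an intrinsic value (the
expected KL divergence between post- and pre-observation beliefs, i.e.
expected information gain).  With preference precision ``lambda = 0``
the agent is a pure information seeker; as ``lambda`` grows it becomes
increasingly preference-driven.  Initial-stage EFE propagates the
final-stage EFEs through the inferred transition structure.

Belief updating comes in four variants distinguished by their
forgetting kinetics: surprise-modulated shrinkage of the sampled pair's
concentrations (predictive surprise mapped through an adaptation rate),
static decay of the sampled pair toward the prior, and static decay of
the three unsampled pairs toward the prior.  The Full variant has all
three; NPS drops surprise-based learning, NSD the sampled-pair decay,
NUD the unsampled-pair decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import betaln, digamma

from .task import TrialRecord
from .transition import TransitionCounts, TransitionStructure, infer_structure, update_counts

__all__ = [
    "VARIANTS",
    "AiParams",
    "BeliefState",
    "ActiveInferenceAgent",
    "predictive_outcome_prob",
    "preference_log_prob",
    "beta_kl",
    "efe_final",
    "efe_initial",
    "habit_bias",
    "ai_policy",
    "predictive_surprise",
    "bayes_factor_surprise",
    "adaptation_rate",
    "update_beliefs",
]

VARIANTS = ("full", "nud", "nsd", "nps")

CONC_FLOOR = 1e-6


@dataclass(frozen=True)
class AiParams:
    """Free parameters of the active-inference agent.

    ``pref_lambda`` is the preference precision (0 = pure information
    seeking, bounded at 10), ``kappa`` the habit precision for repeating
    the previous initial-stage action, ``gamma1``/``gamma2`` inverse
    temperatures, ``prior_mean`` the mean of the prior Beta over outcome
    probabilities (total concentration fixed at 2), ``learn_rate`` the
    increment scale of belief updates, and ``nu_ps``/``nu_sd``/``nu_ud``
    the prior-volatility parameters of the three forgetting kinetics.
    The ``variant`` pins the corresponding nu to zero.
    """

    pref_lambda: float = 1.0
    kappa: float = 0.0
    gamma1: float = 5.0
    gamma2: float = 5.0
    prior_mean: float = 0.5
    learn_rate: float = 1.0
    nu_ps: float = 0.0
    nu_sd: float = 0.0
    nu_ud: float = 0.0
    variant: str = "full"
    prior_pull: bool = False  # restore the chi*alpha0 pull in surprise updates

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 <= self.pref_lambda:
            raise ValueError("pref_lambda must be >= 0")
        if not 0.0 < self.prior_mean < 1.0:
            raise ValueError("prior_mean must be in (0, 1)")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be > 0")
        for name in ("nu_ps", "nu_sd", "nu_ud"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("inverse temperatures must be >= 0")

    def effective_nus(self) -> tuple[float, float, float]:
        """(nu_ps, nu_sd, nu_ud) with the variant's omitted kinetic zeroed."""
        nu_ps, nu_sd, nu_ud = self.nu_ps, self.nu_sd, self.nu_ud
        if self.variant == "nps":
            nu_ps = 0.0
        elif self.variant == "nsd":
            nu_sd = 0.0
        elif self.variant == "nud":
            nu_ud = 0.0
        return nu_ps, nu_sd, nu_ud


@dataclass
class BeliefState:
    """Beta concentrations over the four final-stage (state, action) pairs.

    ``alpha``/``beta`` are 2x2 arrays indexed [state-1, action];
    ``alpha0``/``beta0`` are the prior concentrations the beliefs decay
    toward (total prior concentration 2, mean = prior_mean).
    """

    alpha: np.ndarray
    beta: np.ndarray
    alpha0: float
    beta0: float

    @classmethod
    def from_prior(cls, prior_mean: float) -> "BeliefState":
        a0 = 2.0 * prior_mean
        b0 = 2.0 - a0
        return cls(np.full((2, 2), a0), np.full((2, 2), b0), a0, b0)

    def copy(self) -> "BeliefState":
        return BeliefState(self.alpha.copy(), self.beta.copy(), self.alpha0, self.beta0)


def predictive_outcome_prob(belief: BeliefState, s: int, a: int) -> float:
    """Predictive probability of o=1 for pair (state s, action a): the Beta mean."""
    al = belief.alpha[s - 1, a]
    be = belief.beta[s - 1, a]
    return float(al / (al + be))


def preference_log_prob(pref_lambda: float) -> tuple[float, float]:
    """Log preference probabilities (ln p(o=0|C), ln p(o=1|C)).

    The preference over the binary outcome is a Bernoulli kernel
    p(o|C) ~ exp(o*lambda) exp(-(1-o)*lambda); at lambda=0 both outcomes
    are valued equally.
    """
    lam = float(pref_lambda)
    ln_z = np.logaddexp(lam, -lam)
    return float(-lam - ln_z), float(lam - ln_z)


def beta_kl(post_alpha: float, post_beta: float, prior_alpha: float, prior_beta: float) -> float:
    """KL divergence KL(Beta(post) || Beta(prior)) in nats, closed form."""
    a1, b1, a2, b2 = post_alpha, post_beta, prior_alpha, prior_beta
    if min(a1, b1, a2, b2) <= 0:
        raise ValueError("Beta concentrations must be > 0")
    return float(
        betaln(a2, b2)
        - betaln(a1, b1)
        + (a1 - a2) * digamma(a1)
        + (b1 - b2) * digamma(b1)
        + (a2 - a1 + b2 - b1) * digamma(a1 + b1)
    )


def efe_final(belief: BeliefState, s: int, pref_lambda: float) -> np.ndarray:
    """Expected free energy of the two actions in final-stage state ``s``.

    G(a) = -E_q[ln p(o|C)] - E_q[KL(posterior-after-o || current)]
    where q is the predictive outcome distribution and the hypothetical
    posterior is the one-step conjugate update (unit increment).  Lower
    G is better.
    """
    ln_p0, ln_p1 = preference_log_prob(pref_lambda)
    g = np.empty(2)
    for a in (0, 1):
        al = float(belief.alpha[s - 1, a])
        be = float(belief.beta[s - 1, a])
        q1 = al / (al + be)
        extrinsic = q1 * ln_p1 + (1.0 - q1) * ln_p0
        intrinsic = q1 * beta_kl(al + 1.0, be, al, be) + (1.0 - q1) * beta_kl(al, be + 1.0, al, be)
        g[a] = -extrinsic - intrinsic
    return g


def efe_initial(g_final: np.ndarray, structure: TransitionStructure) -> np.ndarray:
    """Initial-stage EFE: transition-weighted sums of final-stage EFEs.

    G(a) = p(s_B|a) * (G(s_B,a_A) + G(s_B,a_B)) + p(s_C|a) * (...), with
    plain sums over the actions available in each final state.
    """
    g_final = np.asarray(g_final, dtype=float).reshape(2, 2)
    sums = g_final.sum(axis=1)  # per final state
    p_sB = structure.p_sB_given_action
    return p_sB * sums[0] + (1.0 - p_sB) * sums[1]


def habit_bias(kappa: float, prev_a1: Optional[int]) -> np.ndarray:
    """Static habit bias toward repeating the previous initial-stage action.

    Bernoulli kernel in the repeat indicator with precision kappa; zero
    on the first trial (no previous action) and always zero at the
    final stage.
    """
    if prev_a1 is None:
        return np.zeros(2)
    z = np.exp(kappa) + np.exp(-kappa)
    e = np.full(2, np.exp(-kappa) / z)
    e[prev_a1] = np.exp(kappa) / z
    return e


def ai_policy(g: np.ndarray, gamma: float, e_a: Optional[np.ndarray] = None) -> np.ndarray:
    """Softmax action probabilities over -gamma*G + habit bias."""
    z = -gamma * np.asarray(g, dtype=float)
    if e_a is not None:
        z = z + np.asarray(e_a, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def predictive_surprise(belief: BeliefState, s: int, a: int, o: int) -> float:
    """Negative log predictive probability of the observed outcome."""
    q1 = predictive_outcome_prob(belief, s, a)
    p = q1 if o == 1 else 1.0 - q1
    return float(-np.log(max(p, 1e-300)))


def bayes_factor_surprise(belief: BeliefState, s: int, a: int, o: int) -> float:
    """Ratio of prior-predictive to current-predictive probability of ``o``."""
    q1 = predictive_outcome_prob(belief, s, a)
    p_cur = q1 if o == 1 else 1.0 - q1
    q1_prior = belief.alpha0 / (belief.alpha0 + belief.beta0)
    p_prior = q1_prior if o == 1 else 1.0 - q1_prior
    return float(p_prior / max(p_cur, 1e-300))


def adaptation_rate(surprise: float, nu: float) -> float:
    """Surprise-modulated adaptation rate chi = m*S / (1 + m*S), m = nu/(1-nu)."""
    if surprise < 0:
        raise ValueError("surprise must be >= 0")
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must be in [0, 1)")
    m = nu / (1.0 - nu)
    ms = m * surprise
    return float(ms / (1.0 + ms))


def update_beliefs(belief: BeliefState, trial: TrialRecord, params: AiParams) -> BeliefState:
    """One trial's belief update (in place), respecting the learning variant.

    Sampled pair: surprise-modulated shrinkage (rate chi from predictive
    surprise and nu_ps) plus the learning-rate-scaled outcome increment,
    then static decay toward the prior at rate nu_sd.  Unsampled pairs:
    static decay toward the prior at rate nu_ud.  All concentrations are
    floored at 1e-6.
    """
    nu_ps, nu_sd, nu_ud = params.effective_nus()
    s_idx, a_obs, o = trial.s2 - 1, trial.a2, trial.o
    l = params.learn_rate

    chi = adaptation_rate(predictive_surprise(belief, trial.s2, a_obs, o), nu_ps)
    al = belief.alpha[s_idx, a_obs]
    be = belief.beta[s_idx, a_obs]
    pull_a = chi * belief.alpha0 if params.prior_pull else 0.0
    pull_b = chi * belief.beta0 if params.prior_pull else 0.0
    al = (1.0 - chi) * al + pull_a + o * l
    be = (1.0 - chi) * be + pull_b + (1 - o) * l
    # static decay of the sampled pair
    al = (1.0 - nu_sd) * al + nu_sd * belief.alpha0
    be = (1.0 - nu_sd) * be + nu_sd * belief.beta0
    belief.alpha[s_idx, a_obs] = max(al, CONC_FLOOR)
    belief.beta[s_idx, a_obs] = max(be, CONC_FLOOR)

    for si in (0, 1):
        for ai in (0, 1):
            if si == s_idx and ai == a_obs:
                continue
            belief.alpha[si, ai] = max(
                (1.0 - nu_ud) * belief.alpha[si, ai] + nu_ud * belief.alpha0, CONC_FLOOR
            )
            belief.beta[si, ai] = max(
                (1.0 - nu_ud) * belief.beta[si, ai] + nu_ud * belief.beta0, CONC_FLOOR
            )
    return belief


class ActiveInferenceAgent:
    """Stateful active-inference agent implementing the simulation contract."""

    def __init__(self, params: AiParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.belief = BeliefState.from_prior(self.params.prior_mean)
        self.counts = TransitionCounts()
        self.prev_a1: Optional[int] = None

    @property
    def structure(self) -> TransitionStructure:
        return infer_structure(self.counts)

    def act(self, stage: int, state: int) -> np.ndarray:
        p = self.params
        if stage == 1:
            g2 = np.vstack([efe_final(self.belief, 1, p.pref_lambda),
                            efe_final(self.belief, 2, p.pref_lambda)])
            g1 = efe_initial(g2, self.structure)
            return ai_policy(g1, p.gamma1, habit_bias(p.kappa, self.prev_a1))
        return ai_policy(efe_final(self.belief, state, p.pref_lambda), p.gamma2)

    def learn(self, trial: TrialRecord) -> None:
        update_counts(self.counts, trial.a1, trial.s2)
        update_beliefs(self.belief, trial, self.params)
        self.prev_a1 = trial.a1
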