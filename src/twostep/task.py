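"""Generative two-step task environment.

The task has a single initial-stage state ``s_A`` with two actions; each
action leads with probability 0.7 to one of two final-stage states
(``s_B``, ``s_C``) and with probability 0.3 to the other, with mirrored
mappings for the two actions.  Each final-stage state offers two actions
whose binary-outcome probabilities drift as independent Gaussian random
walks with reflecting boundaries.

Encodings used throughout the package: actions ``a_A=0, a_B=1``; states
``s_A=0, s_B=1, s_C=2``.  Outcome ``o=1`` codes the preferred event
(reward delivered, or shock absent for aversive variants).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "OutcomeWalks",
    "TrialRecord",
    "SessionData",
    "Agent",
    "init_walks",
    "step_walks",
    "reflect",
    "sample_transition",
    "transition_label",
    "run_session",
]

#: canonical ordering of the four final-stage (state, action) pairs:
#: (s_B, a_A), (s_B, a_B), (s_C, a_A), (s_C, a_B) — a 2x2 array indexed
#: [state - 1, action].
PAIR_SHAPE = (2, 2)

COMMON_P = 0.7
RARE_P = 0.3


@dataclass(frozen=True)
class TaskConfig:
    """Static parameters of one two-step session.

    Parameters
    ----------
    walk_sd
        Standard deviation of the Gaussian random-walk increment, in
        probability units (0.025 for reward paradigms, 0.2 for the
        aversive variant).
    walk_bounds
        Reflecting boundaries ``(lo, hi)`` of the outcome probabilities
        ([0.25, 0.75] or [0, 1]).
    common_dest_of_a0
        Final-stage state (1 or 2) that action 0 reaches with p=0.7.
        Action 1's mapping is mirrored.
    n_trials
        Number of trials in the session.
    outcome_is_preferred
        True when outcome 1 codes the preferred event.  Kept for
        datasets where the raw log codes shocks; the canonical schema
        always stores o=1 as preferred.
    init_walks_at_center
        If True initialise all walks at the midpoint of the bounds
        instead of drawing them uniformly.
    seed
        Base seed for the environment's random stream.
    """

    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    common_dest_of_a0: int = 1
    n_trials: int = 201
    outcome_is_preferred: bool = True
    init_walks_at_center: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.walk_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"walk_bounds must satisfy 0 <= lo <= hi <= 1, got {self.walk_bounds}")
        if lo == hi and self.walk_sd > 0 and lo not in (0.0, 1.0):
            pass  # degenerate interval is allowed: walk pins to the single value
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be >= 0")
        if self.common_dest_of_a0 not in (1, 2):
            raise ValueError("common_dest_of_a0 must be state 1 or 2")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")

    @property
    def p_sB_given_action(self) -> np.ndarray:
        """p(s2 = s_B | a1) for actions 0 and 1 under the true structure."""
        if self.common_dest_of_a0 == 1:
            return np.array([COMMON_P, RARE_P])
        return np.array([RARE_P, COMMON_P])


@dataclass
class OutcomeWalks:
    """Generative Bernoulli outcome probabilities, indexed [state-1, action]."""

    theta2: np.ndarray  # shape (2, 2)

    def copy(self) -> "OutcomeWalks":
        return OutcomeWalks(self.theta2.copy())


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial of the two-step task."""

    t: int
    a1: int
    s2: int  # 1 (s_B) or 2 (s_C)
    transition: int  # 1 common, 0 rare
    a2: int
    o: int  # 0 or 1; 1 is the preferred event


@dataclass
class SessionData:
    """A subject's ordered trial list plus the task configuration."""

    config: TaskConfig
    trials: list[TrialRecord]
    walks: Optional[np.ndarray] = None  # (n_trials, 2, 2) generative theta2
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trials, start=1):
            if tr.t != i:
                raise ValueError(f"trial indices must be contiguous from 1; got {tr.t} at position {i}")

    def __len__(self) -> int:
        return len(self.trials)

    def arrays(self) -> dict[str, np.ndarray]:
        """Column arrays (a1, s2, a2, o, transition), for vectorised code."""
        return {
            "a1": np.array([tr.a1 for tr in self.trials], dtype=np.int64),
            "s2": np.array([tr.s2 for tr in self.trials], dtype=np.int64),
            "a2": np.array([tr.a2 for tr in self.trials], dtype=np.int64),
            "o": np.array([tr.o for tr in self.trials], dtype=np.int64),
            "transition": np.array([tr.transition for tr in self.trials], dtype=np.int64),
        }


class Agent(Protocol):
    """Contract a behaving agent must satisfy for closed-loop simulation."""

    def act(self, stage: int, state: int) -> np.ndarray:
        """Action probabilities (length 2) at the given stage and state."""

    def learn(self, trial: TrialRecord) -> None:
        """Update internal state from a completed trial."""

    def reset(self) -> None:
        """Return to the pre-session state."""


def reflect(v: float, lo: float, hi: float) -> float:
    """Mirror-reflect ``v`` into [lo, hi], iterating until inside."""
    if lo == hi:
        return lo
    while v < lo or v > hi:
        if v > hi:
            v = 2.0 * hi - v
        elif v < lo:
            v = 2.0 * lo - v
    return v


def init_walks(config: TaskConfig, rng: np.random.Generator) -> OutcomeWalks:
    """Draw initial outcome probabilities uniformly within the walk bounds."""
    lo, hi = config.walk_bounds
    if config.init_walks_at_center:
        theta = np.full(PAIR_SHAPE, 0.5 * (lo + hi))
    else:
        theta = rng.uniform(lo, hi, size=PAIR_SHAPE)
    return OutcomeWalks(theta)


def step_walks(walks: OutcomeWalks, config: TaskConfig, rng: np.random.Generator) -> OutcomeWalks:
    """One Gaussian-increment step of all four walks with reflecting bounds."""
    lo, hi = config.walk_bounds
    eps = rng.normal(0.0, config.walk_sd, size=PAIR_SHAPE)
    theta = walks.theta2 + eps
    out = np.empty_like(theta)
    for idx in np.ndindex(*PAIR_SHAPE):
        out[idx] = reflect(float(theta[idx]), lo, hi)
    return OutcomeWalks(out)


def transition_label(config: TaskConfig, a1: int, s2: int) -> int:
    """1 if (a1 -> s2) is the common transition under the true structure."""
    common_s2 = config.common_dest_of_a0 if a1 == 0 else (3 - config.common_dest_of_a0)
    return int(s2 == common_s2)


def sample_transition(
    p_sB_given_action: Sequence[float], a1: int, rng: np.random.Generator
) -> int:
    """Sample the final-stage state (1 or 2) reached by initial action ``a1``."""
    if a1 not in (0, 1):
        raise ValueError(f"unknown action id {a1}")
    p_sB = float(p_sB_given_action[a1])
    return 1 if rng.random() < p_sB else 2


def run_session(
    agent: Agent,
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "sim",
) -> SessionData:
    """Closed-loop simulation of one session.

    Per trial: the agent picks the initial action, the environment samples
    the transition, the agent picks the final action, the environment
    samples the binary outcome from the current walk value, the agent
    updates, and the walks take one step.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    agent.reset()
    walks = init_walks(config, rng)
    p_sB = config.p_sB_given_action
    trials: list[TrialRecord] = []
    traj = np.empty((config.n_trials, 2, 2))
    for t in range(1, config.n_trials + 1):
        p1 = np.asarray(agent.act(1, 0), dtype=float)
        _check_probs(p1)
        a1 = int(rng.random() < p1[1])
        s2 = sample_transition(p_sB, a1, rng)
        p2 = np.asarray(agent.act(2, s2), dtype=float)
        _check_probs(p2)
        a2 = int(rng.random() < p2[1])
        o = int(rng.random() < walks.theta2[s2 - 1, a2])
        trial = TrialRecord(
            t=t, a1=a1, s2=s2, transition=transition_label(config, a1, s2), a2=a2, o=o
        )
        agent.learn(trial)
        traj[t - 1] = walks.theta2
        trials.append(trial)
        walks = step_walks(walks, config, rng)
    return SessionData(config=config, trials=trials, walks=traj, subject_id=subject_id)


def _check_probs(p: np.ndarray) -> None:
    if p.shape != (2,) or not np.all(np.isfinite(p)) or abs(float(p.sum()) - 1.0) > 1e-8 or np.any(p < -1e-12):
        raise ValueError(f"agent emitted invalid action probabilities: {p}")
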