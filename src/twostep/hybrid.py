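"""Hybrid model-free / model-based reinforcement-learning agent.

The model-free component is SARSA(lambda) over the two stages; the
model-based component plans initial-stage values through the inferred
transition structure; the two are mixed with weight ``w`` at the initial
stage only (the strategies coincide at the final stage).  Action
selection is softmax with stage-specific inverse temperatures and an
initial-stage stickiness bonus for repeating the previous choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .task import TrialRecord
from .transition import TransitionCounts, TransitionStructure, infer_structure, update_counts

__all__ = [
    "HybridParams",
    "QTable",
    "HybridAgent",
    "mf_prediction_errors",
    "mf_update",
    "mb_values",
    "hybrid_combine",
    "softmax_policy",
]


@dataclass(frozen=True)
class HybridParams:
    """Free parameters of the hybrid agent.

    ``alpha1``/``alpha2`` are stage learning rates, ``elig_lambda`` the
    eligibility parameter passing the final-stage prediction error back
    to the initial-stage pair, ``w`` the model-based weight, ``beta1``/
    ``beta2`` inverse temperatures, ``rho`` initial-stage stickiness.
    """

    alpha1: float = 0.5
    alpha2: float = 0.5
    elig_lambda: float = 0.5
    w: float = 0.5
    beta1: float = 5.0
    beta2: float = 5.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "elig_lambda", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be >= 0")


@dataclass
class QTable:
    """Model-free action values: q1 for the initial stage, q2[state-1, action] for the final."""

    q1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def copy(self) -> "QTable":
        return QTable(self.q1.copy(), self.q2.copy())


def mf_prediction_errors(q: QTable, trial: TrialRecord) -> tuple[float, float]:
    """Stage prediction errors (delta1, delta2) at outcome time.

    delta1 = Q(s2, a2) - Q(s_A, a1): no outcome occurs at the initial
    stage, so its error is the value of the selected final-stage action.
    delta2 = o - Q(s2, a2).
    """
    q2sa = float(q.q2[trial.s2 - 1, trial.a2])
    delta1 = q2sa - float(q.q1[trial.a1])
    delta2 = float(trial.o) - q2sa
    return delta1, delta2


def mf_update(q: QTable, trial: TrialRecord, deltas: tuple[float, float], params: HybridParams) -> QTable:
    """SARSA(lambda) update of the two visited state-action pairs (in place)."""
    delta1, delta2 = deltas
    q.q1[trial.a1] += params.alpha1 * delta1 + params.alpha1 * params.elig_lambda * delta2
    q.q2[trial.s2 - 1, trial.a2] += params.alpha2 * delta2
    return q


def mb_values(q: QTable, structure: TransitionStructure) -> np.ndarray:
    """Model-based initial-stage values planned through the structure.

    Q_MB(s_A, a) = p(s_B|a) max_a' Q(s_B, a') + p(s_C|a) max_a' Q(s_C, a').
    """
    best = q.q2.max(axis=1)  # per final state
    p_sB = structure.p_sB_given_action
    return p_sB * best[0] + (1.0 - p_sB) * best[1]


def hybrid_combine(q_mb: np.ndarray, q_mf: np.ndarray, w: float) -> np.ndarray:
    """Convex mixture of model-based and model-free initial-stage values."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return w * np.asarray(q_mb, dtype=float) + (1.0 - w) * np.asarray(q_mf, dtype=float)


def softmax_policy(
    values: np.ndarray,
    beta: float,
    rho: float = 0.0,
    prev_a1: Optional[int] = None,
    stage: int = 1,
) -> np.ndarray:
    """Softmax choice probabilities with optional initial-stage stickiness.

    p(a) ~ exp(beta * value(a) + rho * rep(a)) where rep(a)=1 iff a
    repeats the previous initial-stage choice; stickiness applies at
    stage 1 only.  Stabilised by max subtraction.
    """
    z = beta * np.asarray(values, dtype=float)
    if stage == 1 and prev_a1 is not None:
        rep = np.zeros(2)
        rep[prev_a1] = 1.0
        z = z + rho * rep
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class HybridAgent:
    """Stateful hybrid RL agent implementing the simulation contract."""

    def __init__(self, params: HybridParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.q = QTable()
        self.counts = TransitionCounts()
        self.prev_a1: Optional[int] = None

    @property
    def structure(self) -> TransitionStructure:
        return infer_structure(self.counts)

    def act(self, stage: int, state: int) -> np.ndarray:
        p = self.params
        if stage == 1:
            q_net = hybrid_combine(mb_values(self.q, self.structure), self.q.q1, p.w)
            return softmax_policy(q_net, p.beta1, p.rho, self.prev_a1, stage=1)
        return softmax_policy(self.q.q2[state - 1], p.beta2, stage=2)

    def learn(self, trial: TrialRecord) -> None:
        update_counts(self.counts, trial.a1, trial.s2)
        deltas = mf_prediction_errors(self.q, trial)
        mf_update(self.q, trial, deltas, self.params)
        self.prev_a1 = trial.a1
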