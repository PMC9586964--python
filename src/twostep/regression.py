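"""Lagged logistic regression of initial-stage choices.

The initial-stage choice on each trial is regressed on the previous
T=4 trials' choices, outcomes, transitions, and the outcome-transition
interaction, all coded +/-1.  A model-free learner repeats rewarded
initial choices regardless of transition (outcome main effect), while
a model-based learner repeats them only after common transitions
(outcome x transition interaction) — the task's designed dissociation.
There is no global intercept; the lagged-choice terms play that role.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .task import SessionData

__all__ = [
    "TERMS",
    "CodedSession",
    "HistoryCoefficients",
    "encode_session",
    "build_design",
    "fit_history_regression",
    "fit_session",
    "average_coefficients",
]

#: regressor families, in design-matrix column order within each lag
TERMS = ("choice", "outcome", "transition", "interaction")


@dataclass
class CodedSession:
    """+/-1 codes per trial: choice, outcome (+1 preferred), transition (+1 common)."""

    y: np.ndarray
    o: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        for name in ("y", "o", "tau"):
            v = getattr(self, name)
            if not np.all(np.isin(v, (-1, 1))):
                raise ValueError(f"{name} must be coded +/-1")
        if not (len(self.y) == len(self.o) == len(self.tau)):
            raise ValueError("code arrays must have equal length")


@dataclass
class HistoryCoefficients:
    """Coefficients indexed [lag-1, term]; log-odds units; lags 1..T."""

    values: np.ndarray  # shape (T, 4)

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]

    def get(self, lag: int, term: str) -> float:
        return float(self.values[lag - 1, TERMS.index(term)])

    def as_frame(self, subject_id: str = "sim") -> pd.DataFrame:
        rows = [
            {"subject_id": subject_id, "lag": lag, "term": term,
             "estimate": self.get(lag, term)}
            for lag in range(1, self.n_lags + 1)
            for term in TERMS
        ]
        return pd.DataFrame(rows)


def encode_session(session: SessionData) -> CodedSession:
    """Code a session's trials as +/-1 per the regression conventions.

    Choices: a_A -> -1, a_B -> +1 (same convention for the response and
    the lagged regressors).  Outcomes: +1 for the preferred event.
    Transitions: +1 common, -1 rare.
    """
    arr = session.arrays()
    y = 2 * arr["a1"] - 1
    o = 2 * arr["o"] - 1
    tau = 2 * arr["transition"] - 1
    return CodedSession(y=y, o=o, tau=tau)


def build_design(coded: CodedSession, T: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response for the lagged regression.

    One row per trial with a complete T-trial history; 4T columns, for
    each lag t-1..t-T the regressors x, o*x, tau*x, o*tau*x.  No
    intercept column.
    """
    n = len(coded.y)
    if n <= T:
        raise ValueError(f"session of length {n} too short for T={T} lags")
    rows = n - T
    X = np.empty((rows, 4 * T))
    for lag in range(1, T + 1):
        sl = slice(T - lag, n - lag)
        x = coded.y[sl]
        base = 4 * (lag - 1)
        X[:, base + 0] = x
        X[:, base + 1] = coded.o[sl] * x
        X[:, base + 2] = coded.tau[sl] * x
        X[:, base + 3] = coded.o[sl] * coded.tau[sl] * x
    y = coded.y[T:]
    return X, y


def fit_history_regression(
    X: np.ndarray, y: np.ndarray, penalty_C: float = 1.0
) -> HistoryCoefficients:
    """L2-penalised logistic regression of the coded response on the design.

    The unit-strength L2 penalty matches the default of the
    general-purpose solver this analysis is standardly run with, and
    guarantees finite coefficients under perfect separation.  Set
    ``penalty_C=np.inf`` for an unpenalised fit.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("response has fewer than 2 distinct values")
    # default solver penalty is ridge (L2); C=inf turns it off
    model = LogisticRegression(C=penalty_C, fit_intercept=False, max_iter=2000)
    model.fit(X, y)
    coef = model.coef_.ravel()
    # sklearn orients coefficients toward classes_[1]; ensure +1 is the target
    if model.classes_[1] == -1:
        coef = -coef
    T = X.shape[1] // 4
    return HistoryCoefficients(coef.reshape(T, 4))


def fit_session(session: SessionData, T: int = 4, penalty_C: float = 1.0) -> HistoryCoefficients:
    """Convenience: encode, build the design, and fit for one session."""
    X, y = build_design(encode_session(session), T)
    return fit_history_regression(X, y, penalty_C)


def average_coefficients(coeffs: Sequence[HistoryCoefficients]) -> HistoryCoefficients:
    """Elementwise mean of coefficient sets (e.g. across simulation runs)."""
    if len(coeffs) == 0:
        raise ValueError("empty coefficient list")
    return HistoryCoefficients(np.mean([c.values for c in coeffs], axis=0))
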