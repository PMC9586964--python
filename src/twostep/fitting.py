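"""Per-subject maximum-likelihood fitting by session replay.

Each model's likelihood replays the subject's session: on every trial
the agent's choice probabilities for the observed stage-1 and stage-2
actions are computed with all internal state conditioned on the
subject's actual history, and their logs accumulated.  Optimisation is
bounded L-BFGS-B from multiple uniform random starts (default 25, as
many as needed to tame local optima in these likelihoods).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .active_inference import ActiveInferenceAgent, AiParams
from .hybrid import HybridAgent, HybridParams
from .task import SessionData

__all__ = [
    "ParameterSpec",
    "FitResult",
    "MODELS",
    "make_agent",
    "session_neg_log_likelihood",
    "replay_neg_log_likelihood",
    "fit_subject",
    "information_criteria",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ParameterSpec:
    """Names and box bounds of a model's free parameters."""

    model_id: str
    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.names)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def to_dict(self, x: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.names, map(float, x)))


def _hybrid_spec(model_id: str, names: Sequence[str]) -> ParameterSpec:
    bounds = {
        "alpha1": (0.0, 1.0),
        "alpha2": (0.0, 1.0),
        "elig_lambda": (0.0, 1.0),
        "w": (0.0, 1.0),
        "beta1": (0.0, 20.0),
        "beta2": (0.0, 20.0),
        "rho": (-5.0, 5.0),
    }
    lo, hi = zip(*(bounds[n] for n in names))
    return ParameterSpec(model_id, tuple(names), lo, hi)


def _ai_spec(model_id: str, names: Sequence[str]) -> ParameterSpec:
    bounds = {
        "pref_lambda": (0.0, 10.0),
        "kappa": (-5.0, 5.0),
        "gamma1": (0.0, 20.0),
        "gamma2": (0.0, 20.0),
        "prior_mean": (0.05, 0.95),
        "learn_rate": (0.01, 2.0),
        "nu_ps": (0.0, 0.999),
        "nu_sd": (0.0, 0.999),
        "nu_ud": (0.0, 0.999),
    }
    lo, hi = zip(*(bounds[n] for n in names))
    return ParameterSpec(model_id, tuple(names), lo, hi)


_HYBRID_FULL = ("alpha1", "alpha2", "elig_lambda", "w", "beta1", "beta2", "rho")
_AI_FULL = (
    "pref_lambda",
    "kappa",
    "gamma1",
    "gamma2",
    "prior_mean",
    "learn_rate",
    "nu_ps",
    "nu_sd",
    "nu_ud",
)

#: model registry: spec plus the parameters pinned by the variant
MODELS: dict[str, ParameterSpec] = {
    "hybrid": _hybrid_spec("hybrid", _HYBRID_FULL),
    # pure strategies, used for degeneracy checks and as cheap baselines
    "mf": _hybrid_spec("mf", ("alpha1", "alpha2", "elig_lambda", "beta1", "beta2", "rho")),
    "mb": _hybrid_spec("mb", ("alpha2", "beta1", "beta2", "rho")),
    "ai_full": _ai_spec("ai_full", _AI_FULL),
    "ai_nud": _ai_spec("ai_nud", tuple(n for n in _AI_FULL if n != "nu_ud")),
    "ai_nsd": _ai_spec("ai_nsd", tuple(n for n in _AI_FULL if n != "nu_sd")),
    "ai_nps": _ai_spec("ai_nps", tuple(n for n in _AI_FULL if n != "nu_ps")),
}

_AI_VARIANT = {"ai_full": "full", "ai_nud": "nud", "ai_nsd": "nsd", "ai_nps": "nps"}


def _full_hybrid_params(model_id: str, p: dict[str, float]) -> HybridParams:
    if model_id == "mf":
        p = {**p, "w": 0.0}
    elif model_id == "mb":
        p = {**p, "w": 1.0, "alpha1": 0.0, "elig_lambda": 0.0}
    return HybridParams(**{k: p[k] for k in _HYBRID_FULL})


def _full_ai_params(model_id: str, p: dict[str, float]) -> AiParams:
    variant = _AI_VARIANT[model_id]
    full = {n: p.get(n, 0.0) for n in _AI_FULL}
    return AiParams(variant=variant, **full)


def make_agent(model_id: str, params: dict[str, float]):
    """Instantiate the behaving agent for a model id and parameter dict."""
    if model_id in ("hybrid", "mf", "mb"):
        return HybridAgent(_full_hybrid_params(model_id, params))
    if model_id in _AI_VARIANT:
        return ActiveInferenceAgent(_full_ai_params(model_id, params))
    raise KeyError(f"unknown model id {model_id!r}")


def replay_neg_log_likelihood(agent, session: SessionData) -> float:
    """Reference replay of a session through an agent object (slow path)."""
    agent.reset()
    nll = 0.0
    for trial in session.trials:
        p1 = agent.act(1, 0)
        nll -= math.log(max(float(p1[trial.a1]), PROB_FLOOR))
        p2 = agent.act(2, trial.s2)
        nll -= math.log(max(float(p2[trial.a2]), PROB_FLOOR))
        agent.learn(trial)
    return nll


def session_neg_log_likelihood(
    model_id: str, params: dict[str, float] | Sequence[float], session: SessionData
) -> float:
    """Negative log likelihood of a subject's choices under a model."""
    spec = MODELS[model_id]
    if not isinstance(params, dict):
        params = spec.to_dict(params)
    arr = session.arrays()
    a1, s2, a2, o = arr["a1"], arr["s2"], arr["a2"], arr["o"]
    if model_id in ("hybrid", "mf", "mb"):
        hp = _full_hybrid_params(model_id, params)
        return float(
            _kernels.hybrid_session_nll(
                a1, s2, a2, o,
                hp.alpha1, hp.alpha2, hp.elig_lambda, hp.w, hp.beta1, hp.beta2, hp.rho,
            )
        )
    ap = _full_ai_params(model_id, params)
    nu_ps, nu_sd, nu_ud = ap.effective_nus()
    return float(
        _kernels.ai_session_nll(
            a1, s2, a2, o,
            ap.pref_lambda, ap.kappa, ap.gamma1, ap.gamma2,
            ap.prior_mean, ap.learn_rate, nu_ps, nu_sd, nu_ud, ap.prior_pull,
        )
    )


@dataclass
class FitResult:
    """Outcome of a per-subject maximum-likelihood fit."""

    model_id: str
    subject_id: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n_trials: int
    n_restarts: int
    seed: int
    restart_logliks: list[float] = field(default_factory=list)


def information_criteria(max_loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 ln L; BIC = k ln(n) - 2 ln L."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    aic = 2.0 * k - 2.0 * max_loglik
    bic = k * math.log(n) - 2.0 * max_loglik
    return aic, bic


def fit_subject(
    model_id: str,
    session: SessionData,
    n_restarts: int = 25,
    seed: int = 0,
    gtol: float = 1e-6,
) -> FitResult:
    """Best-of-restarts bounded ML fit of one model to one session.

    Starting points are independent uniform draws within the parameter
    bounds from a stream seeded by ``seed``; the restart with the
    highest log likelihood wins.  The likelihood at every trial uses
    only the subject's actual history, so replay order is exact.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if len(session) == 0:
        raise ValueError("cannot fit an empty session")
    spec = MODELS[model_id]
    rng = np.random.default_rng(seed)
    bounds = list(zip(spec.lower, spec.upper))
    arr = session.arrays()
    a1, s2, a2, o = arr["a1"], arr["s2"], arr["a2"], arr["o"]

    if model_id in ("hybrid", "mf", "mb"):
        def nll_vec(x: np.ndarray) -> float:
            hp = _full_hybrid_params(model_id, spec.to_dict(x))
            return _kernels.hybrid_session_nll(
                a1, s2, a2, o,
                hp.alpha1, hp.alpha2, hp.elig_lambda, hp.w, hp.beta1, hp.beta2, hp.rho,
            )
    else:
        variant = _AI_VARIANT[model_id]
        def nll_vec(x: np.ndarray) -> float:
            p = spec.to_dict(x)
            full = {n: p.get(n, 0.0) for n in _AI_FULL}
            if variant == "nps":
                full["nu_ps"] = 0.0
            elif variant == "nsd":
                full["nu_sd"] = 0.0
            elif variant == "nud":
                full["nu_ud"] = 0.0
            return _kernels.ai_session_nll(
                a1, s2, a2, o,
                full["pref_lambda"], full["kappa"], full["gamma1"], full["gamma2"],
                full["prior_mean"], full["learn_rate"],
                full["nu_ps"], full["nu_sd"], full["nu_ud"], False,
            )

    best_x: Optional[np.ndarray] = None
    best_nll = np.inf
    restart_lls: list[float] = []
    for _ in range(n_restarts):
        x0 = rng.uniform(spec.lower, spec.upper)
        try:
            res = minimize(
                nll_vec, x0, method="L-BFGS-B", bounds=bounds, options={"gtol": gtol}
            )
            val, xh = float(res.fun), spec.clip(res.x)
        except Exception:
            val, xh = float(nll_vec(x0)), x0
        restart_lls.append(-val)
        if val < best_nll:
            best_nll, best_x = val, xh
    if best_x is None or not np.isfinite(best_nll):
        raise RuntimeError(f"all {n_restarts} restarts failed for {model_id}")
    loglik = -best_nll
    aic, bic = information_criteria(loglik, spec.k, len(session))
    return FitResult(
        model_id=model_id,
        subject_id=session.subject_id,
        params=spec.to_dict(best_x),
        loglik=loglik,
        aic=aic,
        bic=bic,
        n_trials=len(session),
        n_restarts=n_restarts,
        seed=seed,
        restart_logliks=restart_lls,
    )
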