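"""Random-effects Bayesian model selection.

Treats the model identity of each subject as a random effect drawn from
a population distribution with Dirichlet-distributed frequencies and
estimates that distribution by variational Bayes (the standard
Dirichlet scheme of Stephan et al. 2009).  Reports expected posterior
model frequencies, exceedance probabilities (the probability that a
model is the most frequent), and protected exceedance probabilities,
which blend the exceedance probabilities with a uniform distribution
according to the Bayesian omnibus risk — the posterior probability that
all models are equally frequent (Rigoux et al. 2014).  Family-level
inference uses "F-unity" priors that give each family one unit of
prior mass split over its members, with the exact posterior drawn by
Gibbs sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .fitting import FitResult

__all__ = [
    "EvidenceMatrix",
    "BmsResult",
    "evidence_from_criteria",
    "rfx_bms",
    "exceedance_probabilities",
    "protected_xp",
    "family_comparison",
]


@dataclass
class EvidenceMatrix:
    """Subjects x models approximate log model evidences (-AIC/2 or -BIC/2)."""

    log_evidence: np.ndarray
    model_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    criterion: str = "aic"

    def __post_init__(self) -> None:
        le = np.asarray(self.log_evidence, dtype=float)
        if le.ndim != 2 or le.shape != (len(self.subject_ids), len(self.model_ids)):
            raise ValueError("log_evidence must be (n_subjects, n_models)")
        if not np.all(np.isfinite(le)):
            raise ValueError("log evidences must be finite")
        self.log_evidence = le


@dataclass
class BmsResult:
    """Posterior of the random-effects model-frequency analysis."""

    alpha: np.ndarray  # posterior Dirichlet concentrations
    prior_alpha: np.ndarray
    expected_r: np.ndarray  # <r> = alpha / sum(alpha)
    subject_posteriors: np.ndarray  # (n_subjects, n_models)
    model_ids: tuple[str, ...]
    xp: Optional[np.ndarray] = None
    pxp: Optional[np.ndarray] = None
    bor: Optional[float] = None
    n_iter: int = 0


def evidence_from_criteria(
    fit_grid: Sequence[Sequence[FitResult]],
    criterion: str = "aic",
) -> EvidenceMatrix:
    """Assemble the log-evidence matrix from a subjects x models fit grid."""
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    subject_ids = tuple(row[0].subject_id for row in fit_grid)
    model_ids = tuple(fr.model_id for fr in fit_grid[0])
    le = np.empty((len(fit_grid), len(model_ids)))
    for i, row in enumerate(fit_grid):
        if tuple(fr.model_id for fr in row) != model_ids:
            raise ValueError("inconsistent model ordering across subjects")
        for j, fr in enumerate(row):
            le[i, j] = -(fr.aic if criterion == "aic" else fr.bic) / 2.0
    return EvidenceMatrix(le, model_ids, subject_ids, criterion)


def rfx_bms(
    evidence: EvidenceMatrix | np.ndarray,
    prior_alpha: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BmsResult:
    """Variational random-effects model selection.

    Iterates the standard updates — per-subject model posteriors
    g_nk ~ exp(log-evidence + digamma(alpha_k) - digamma(sum alpha)),
    alpha_k = prior_k + sum_n g_nk — until max |delta alpha| < tol.
    """
    if isinstance(evidence, EvidenceMatrix):
        le = evidence.log_evidence
        model_ids = evidence.model_ids
    else:
        le = np.asarray(evidence, dtype=float)
        model_ids = tuple(f"m{j}" for j in range(le.shape[1]))
    if le.ndim != 2 or le.shape[0] < 1 or le.shape[1] < 2:
        raise ValueError("need >= 1 subject and >= 2 models")
    if not np.all(np.isfinite(le)):
        raise ValueError("log evidences must be finite")
    n, K = le.shape
    alpha0 = np.ones(K) if prior_alpha is None else np.asarray(prior_alpha, dtype=float)
    alpha = alpha0.copy()
    g = np.full((n, K), 1.0 / K)
    it = 0
    for it in range(1, max_iter + 1):
        logu = le + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return BmsResult(
        alpha=alpha,
        prior_alpha=alpha0,
        expected_r=alpha / alpha.sum(),
        subject_posteriors=g,
        model_ids=model_ids,
        n_iter=it,
    )


def exceedance_probabilities(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
    groups: Optional[Sequence[Sequence[int]]] = None,
) -> np.ndarray:
    """Monte-Carlo P(r_k > r_j for all j != k) from Dirichlet draws.

    With ``groups``, frequencies are first summed within each group
    (family-level exceedance).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be > 0")
    rng = np.random.default_rng(seed)
    xp_counts = None
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        r = rng.dirichlet(alpha, size=m)
        if groups is not None:
            r = np.stack([r[:, list(gidx)].sum(axis=1) for gidx in groups], axis=1)
        winners = np.bincount(np.argmax(r, axis=1), minlength=r.shape[1])
        xp_counts = winners if xp_counts is None else xp_counts + winners
        remaining -= m
    return xp_counts / n_samples


def _dirichlet_neg_entropy_terms(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0)), closed form."""
    asum = alpha.sum()
    return float(
        gammaln(asum)
        - gammaln(alpha).sum()
        - gammaln(alpha0.sum())
        + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(asum))).sum()
    )


def protected_xp(
    evidence: EvidenceMatrix | np.ndarray,
    bms_result: BmsResult,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Protected exceedance probabilities and Bayesian omnibus risk.

    The omnibus risk compares the free energy of the random-effects
    model against the exact evidence of the null in which every model is
    equally frequent; pxp_k = xp_k (1 - bor) + bor / K.
    """
    le = evidence.log_evidence if isinstance(evidence, EvidenceMatrix) else np.asarray(evidence, float)
    n, K = le.shape
    alpha, alpha0, g = bms_result.alpha, bms_result.prior_alpha, bms_result.subject_posteriors
    # F1: variational free energy of the alternative (frequencies ~ Dirichlet)
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_g = -np.where(g > 0, g * np.log(g), 0.0).sum()
    f1 = float((g * (le + e_ln_r)).sum() + ent_g - _dirichlet_neg_entropy_terms(alpha, alpha0))
    # F0: exact log evidence of the null (all frequencies = 1/K)
    f0 = float(logsumexp(le, axis=1).sum() - n * np.log(K))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    xp = bms_result.xp
    if xp is None:
        xp = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)
    pxp = xp * (1.0 - bor) + bor / K
    return pxp, bor


def _gibbs_frequencies(
    le: np.ndarray,
    prior_alpha: np.ndarray,
    n_samples: int,
    burn_in: int,
    seed: int,
) -> np.ndarray:
    """Gibbs samples of the population model frequencies r.

    Alternates r ~ Dirichlet(prior + assignment counts) with per-subject
    model assignments m_n ~ Cat(r_k * evidence_nk).  Samples the exact
    posterior, which matters with non-uniform priors where the
    variational scheme is biased toward models with larger prior mass.
    """
    rng = np.random.default_rng(seed)
    n, K = le.shape
    u = np.exp(le - le.max(axis=1, keepdims=True))
    counts = np.zeros(K)
    samples = np.empty((n_samples, K))
    r = rng.dirichlet(prior_alpha)
    for it in range(burn_in + n_samples):
        w = u * r  # (n, K) unnormalised assignment probabilities
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        draws = rng.random((n, 1))
        assign = (draws > cum).sum(axis=1)
        counts = np.bincount(assign, minlength=K).astype(float)
        r = rng.dirichlet(prior_alpha + counts)
        if it >= burn_in:
            samples[it - burn_in] = r
    return samples


def family_comparison(
    evidence: EvidenceMatrix,
    families: dict[str, Sequence[str]],
    n_samples: int = 20_000,
    burn_in: int = 2_000,
    seed: int = 0,
) -> dict:
    """Family-level random-effects comparison with F-unity priors.

    Each family receives one unit of prior Dirichlet mass, split evenly
    over its member models, so families are a priori equally likely
    regardless of how many models they contain.  The posterior over
    frequencies is drawn by Gibbs sampling (the variational scheme is
    unreliable under non-uniform priors); family frequencies are sums of
    member frequencies and family exceedance probabilities are the
    fractions of samples in which each family is the most frequent.
    (Protected exceedance is a model-level construct and is not defined
    for families.)
    """
    model_index = {m: j for j, m in enumerate(evidence.model_ids)}
    seen: set[str] = set()
    groups = []
    for fam, members in families.items():
        idx = []
        for m in members:
            if m in seen:
                raise ValueError(f"model {m!r} appears in more than one family")
            if m not in model_index:
                raise ValueError(f"model {m!r} not in the evidence matrix")
            seen.add(m)
            idx.append(model_index[m])
        groups.append(idx)
    if seen != set(evidence.model_ids):
        raise ValueError("families must partition the full model set")
    prior = np.empty(len(evidence.model_ids))
    for gidx in groups:
        prior[list(gidx)] = 1.0 / len(gidx)
    samples = _gibbs_frequencies(evidence.log_evidence, prior, n_samples, burn_in, seed)
    fam_samples = np.stack([samples[:, list(gidx)].sum(axis=1) for gidx in groups], axis=1)
    fam_r = fam_samples.mean(axis=0)
    fam_xp = np.bincount(np.argmax(fam_samples, axis=1), minlength=len(groups)) / n_samples
    return {
        "families": list(families.keys()),
        "family_expected_r": fam_r,
        "family_xp": fam_xp,
        "model_expected_r": samples.mean(axis=0),
        "prior_alpha": prior,
    }
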