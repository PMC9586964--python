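"""Compiled session-replay likelihood kernels.

Model fitting evaluates the session log likelihood thousands of times
per subject (25 restarts x quasi-Newton iterations x numerical
gradients), so the replay loop is compiled with numba.  The kernels
implement exactly the same algorithm as the agent classes in
``hybrid.py`` and ``active_inference.py``; the test suite asserts
agreement with the pure-Python replay to 1e-9.

Special functions are implemented locally (numba cannot call scipy):
``lgamma`` comes from the C library via ``math``; digamma uses the
standard recurrence plus asymptotic series, accurate to ~1e-12.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["hybrid_session_nll", "ai_session_nll", "nb_digamma", "nb_beta_kl"]

_LP7 = math.log(0.7)
_LP3 = math.log(0.3)
_TIE_TOL = 1e-9
_P_FLOOR = 1e-12
_CONC_FLOOR = 1e-6


@njit(cache=True)
def nb_digamma(x: float) -> float:
    res = 0.0
    while x < 10.0:
        res -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    res += math.log(x) - 0.5 * inv - inv2 * (
        1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 * (1.0 / 252.0 - inv2 / 240.0))
    )
    return res


@njit(cache=True)
def _betaln(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def nb_beta_kl(a1: float, b1: float, a2: float, b2: float) -> float:
    return (
        _betaln(a2, b2)
        - _betaln(a1, b1)
        + (a1 - a2) * nb_digamma(a1)
        + (b1 - b2) * nb_digamma(b1)
        + (a2 - a1 + b2 - b1) * nb_digamma(a1 + b1)
    )


@njit(cache=True)
def _infer_p_sB(c00: float, c01: float, c10: float, c11: float) -> tuple[float, float]:
    """Most likely mirrored transition structure from counts; flat on ties."""
    ll_a = c00 * _LP7 + c01 * _LP3 + c10 * _LP3 + c11 * _LP7
    ll_b = c00 * _LP3 + c01 * _LP7 + c10 * _LP7 + c11 * _LP3
    if abs(ll_a - ll_b) <= _TIE_TOL:
        return 0.5, 0.5
    if ll_a > ll_b:
        return 0.7, 0.3
    return 0.3, 0.7


@njit(cache=True)
def _softmax2_logp(z0: float, z1: float, choice: int) -> float:
    """Log probability of ``choice`` under a 2-way softmax of (z0, z1)."""
    m = z0 if z0 > z1 else z1
    e0 = math.exp(z0 - m)
    e1 = math.exp(z1 - m)
    p = (e0 if choice == 0 else e1) / (e0 + e1)
    if p < _P_FLOOR:
        p = _P_FLOOR
    return math.log(p)


@njit(cache=True)
def hybrid_session_nll(
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    o: np.ndarray,
    alpha1: float,
    alpha2: float,
    elig_lambda: float,
    w: float,
    beta1: float,
    beta2: float,
    rho: float,
) -> float:
    n = a1.shape[0]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    c00 = c01 = c10 = c11 = 0.0
    prev = -1
    nll = 0.0
    for t in range(n):
        p0, p1 = _infer_p_sB(c00, c01, c10, c11)
        best_b = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        best_c = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p0 * best_b + (1.0 - p0) * best_c
        qmb1 = p1 * best_b + (1.0 - p1) * best_c
        qn0 = w * qmb0 + (1.0 - w) * q1[0]
        qn1 = w * qmb1 + (1.0 - w) * q1[1]
        z0 = beta1 * qn0
        z1 = beta1 * qn1
        if prev == 0:
            z0 += rho
        elif prev == 1:
            z1 += rho
        nll -= _softmax2_logp(z0, z1, a1[t])
        si = s2[t] - 1
        nll -= _softmax2_logp(beta2 * q2[si, 0], beta2 * q2[si, 1], a2[t])
        # learning
        if a1[t] == 0:
            if si == 0:
                c00 += 1.0
            else:
                c01 += 1.0
        else:
            if si == 0:
                c10 += 1.0
            else:
                c11 += 1.0
        q2sa = q2[si, a2[t]]
        delta1 = q2sa - q1[a1[t]]
        delta2 = o[t] - q2sa
        q1[a1[t]] += alpha1 * delta1 + alpha1 * elig_lambda * delta2
        q2[si, a2[t]] += alpha2 * delta2
        prev = a1[t]
    return nll


@njit(cache=True)
def _efe_pair(al: float, be: float, ln_p0: float, ln_p1: float) -> float:
    """Expected free energy of one final-stage pair under current beliefs."""
    q1 = al / (al + be)
    extrinsic = q1 * ln_p1 + (1.0 - q1) * ln_p0
    intrinsic = q1 * nb_beta_kl(al + 1.0, be, al, be) + (1.0 - q1) * nb_beta_kl(
        al, be + 1.0, al, be
    )
    return -extrinsic - intrinsic


@njit(cache=True)
def ai_session_nll(
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    o: np.ndarray,
    lam: float,
    kappa: float,
    gamma1: float,
    gamma2: float,
    prior_mean: float,
    learn_rate: float,
    nu_ps: float,
    nu_sd: float,
    nu_ud: float,
    prior_pull: bool,
) -> float:
    n = a1.shape[0]
    a0 = 2.0 * prior_mean
    b0 = 2.0 - a0
    alpha = np.full((2, 2), a0)
    beta = np.full((2, 2), b0)
    c00 = c01 = c10 = c11 = 0.0
    prev = -1
    nll = 0.0
    ln_z = max(lam, -lam) + math.log(math.exp(lam - max(lam, -lam)) + math.exp(-lam - max(lam, -lam)))
    ln_p0 = -lam - ln_z
    ln_p1 = lam - ln_z
    zk = math.exp(kappa) + math.exp(-kappa)
    e_rep = math.exp(kappa) / zk
    e_non = math.exp(-kappa) / zk
    m_ps = nu_ps / (1.0 - nu_ps)
    g2 = np.empty((2, 2))
    for t in range(n):
        p0, p1 = _infer_p_sB(c00, c01, c10, c11)
        for si in range(2):
            for ai in range(2):
                g2[si, ai] = _efe_pair(alpha[si, ai], beta[si, ai], ln_p0, ln_p1)
        sum_b = g2[0, 0] + g2[0, 1]
        sum_c = g2[1, 0] + g2[1, 1]
        g1_0 = p0 * sum_b + (1.0 - p0) * sum_c
        g1_1 = p1 * sum_b + (1.0 - p1) * sum_c
        z0 = -gamma1 * g1_0
        z1 = -gamma1 * g1_1
        if prev == 0:
            z0 += e_rep
            z1 += e_non
        elif prev == 1:
            z0 += e_non
            z1 += e_rep
        nll -= _softmax2_logp(z0, z1, a1[t])
        si = s2[t] - 1
        nll -= _softmax2_logp(-gamma2 * g2[si, 0], -gamma2 * g2[si, 1], a2[t])
        # transition counts
        if a1[t] == 0:
            if si == 0:
                c00 += 1.0
            else:
                c01 += 1.0
        else:
            if si == 0:
                c10 += 1.0
            else:
                c11 += 1.0
        # belief update, sampled pair
        aa = a2[t]
        al = alpha[si, aa]
        be = beta[si, aa]
        q1 = al / (al + be)
        p_obs = q1 if o[t] == 1 else 1.0 - q1
        if p_obs < 1e-300:
            p_obs = 1e-300
        ps = -math.log(p_obs)
        mps = m_ps * ps
        chi = mps / (1.0 + mps)
        if prior_pull:
            al = (1.0 - chi) * al + chi * a0 + o[t] * learn_rate
            be = (1.0 - chi) * be + chi * b0 + (1 - o[t]) * learn_rate
        else:
            al = (1.0 - chi) * al + o[t] * learn_rate
            be = (1.0 - chi) * be + (1 - o[t]) * learn_rate
        al = (1.0 - nu_sd) * al + nu_sd * a0
        be = (1.0 - nu_sd) * be + nu_sd * b0
        alpha[si, aa] = al if al > _CONC_FLOOR else _CONC_FLOOR
        beta[si, aa] = be if be > _CONC_FLOOR else _CONC_FLOOR
        # unsampled pairs decay toward the prior
        for sj in range(2):
            for aj in range(2):
                if sj == si and aj == aa:
                    continue
                av = (1.0 - nu_ud) * alpha[sj, aj] + nu_ud * a0
                bv = (1.0 - nu_ud) * beta[sj, aj] + nu_ud * b0
                alpha[sj, aj] = av if av > _CONC_FLOOR else _CONC_FLOOR
                beta[sj, aj] = bv if bv > _CONC_FLOOR else _CONC_FLOOR
        prev = a1[t]
    return nll
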