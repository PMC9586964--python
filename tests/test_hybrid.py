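"""Hybrid model-free/model-based agent: value updates and policy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostep.fitting import make_agent, replay_neg_log_likelihood, session_neg_log_likelihood
from twostep.hybrid import (
    HybridParams,
    QTable,
    hybrid_combine,
    mb_values,
    mf_prediction_errors,
    mf_update,
    softmax_policy,
)
from twostep.task import TaskConfig, TrialRecord, run_session
from twostep.transition import TransitionStructure, CANDIDATES


def trial(a1=0, s2=1, a2=0, o=1, t=1):
    return TrialRecord(t=t, a1=a1, s2=s2, transition=1, a2=a2, o=o)


class TestPredictionErrors:
    def test_zero_values_reward(self):
        assert mf_prediction_errors(QTable(), trial(o=1)) == (0.0, 1.0)

    def test_hand_worked_case(self):
        q = QTable()
        q.q1[0] = 0.2
        q.q2[0, 0] = 0.5
        d1, d2 = mf_prediction_errors(q, trial(o=0))
        assert d1 == pytest.approx(0.3)
        assert d2 == pytest.approx(-0.5)

    def test_outcome_at_value_is_fixed_point(self):
        q = QTable()
        q.q2[0, 0] = 1.0
        assert mf_prediction_errors(q, trial(o=1))[1] == 0.0


class TestMfUpdate:
    def test_final_stage_arithmetic(self):
        q = QTable()
        p = HybridParams(alpha2=0.5)
        mf_update(q, trial(o=1), mf_prediction_errors(q, trial(o=1)), p)
        assert q.q2[0, 0] == pytest.approx(0.5)

    def test_eligibility_off_blocks_delta2(self):
        p = HybridParams(alpha1=0.5, alpha2=0.0, elig_lambda=0.0)
        q = QTable()
        mf_update(q, trial(o=1), (0.0, 1.0), p)
        assert q.q1[0] == 0.0

    def test_zero_learning_rates_freeze_values(self):
        p = HybridParams(alpha1=0.0, alpha2=0.0)
        q = QTable()
        mf_update(q, trial(o=1), mf_prediction_errors(q, trial(o=1)), p)
        assert np.all(q.q1 == 0) and np.all(q.q2 == 0)

    def test_only_visited_pairs_change(self):
        p = HybridParams()
        q = QTable()
        mf_update(q, trial(a1=0, s2=1, a2=1, o=1), mf_prediction_errors(q, trial(a1=0, s2=1, a2=1, o=1)), p)
        assert q.q1[1] == 0.0
        assert q.q2[0, 0] == 0.0 and np.all(q.q2[1] == 0)


class TestMbValues:
    def test_planning_through_structure(self):
        q = QTable()
        q.q2[0, 0] = 1.0  # best in s_B = 1, best in s_C = 0
        s = TransitionStructure("a0_common_sB", CANDIDATES["a0_common_sB"])
        np.testing.assert_allclose(mb_values(q, s), [0.7, 0.3])

    def test_flat_structure_symmetric(self):
        q = QTable()
        q.q2 = np.array([[0.9, 0.1], [0.2, 0.4]])
        s = TransitionStructure("flat", CANDIDATES["flat"])
        v = mb_values(q, s)
        assert v[0] == pytest.approx(v[1])

    def test_constant_final_values(self):
        q = QTable()
        q.q2[:] = 0.3
        s = TransitionStructure("a0_common_sB", CANDIDATES["a0_common_sB"])
        np.testing.assert_allclose(mb_values(q, s), [0.3, 0.3])


class TestCombineAndPolicy:
    def test_pure_cases_and_mixture(self):
        q_mb, q_mf = np.array([0.8, 0.1]), np.array([0.2, 0.5])
        np.testing.assert_allclose(hybrid_combine(q_mb, q_mf, 1.0), q_mb)
        np.testing.assert_allclose(hybrid_combine(q_mb, q_mf, 0.0), q_mf)
        assert hybrid_combine(np.array([0.8]), np.array([0.2]), 0.5)[0] == pytest.approx(0.5)

    def test_softmax_closed_form(self):
        p = softmax_policy(np.array([1.0, 0.0]), beta=1.0)
        np.testing.assert_allclose(p, [0.73105858, 0.26894142], atol=1e-8)

    def test_flat_policy_at_zero_beta(self):
        np.testing.assert_allclose(softmax_policy(np.array([3.0, -1.0]), 0.0), [0.5, 0.5])

    @given(st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_shift_invariance(self, c):
        v = np.array([0.4, -1.2])
        p1 = softmax_policy(v, 2.0, rho=0.7, prev_a1=1)
        p2 = softmax_policy(v + c, 2.0, rho=0.7, prev_a1=1)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert p1.sum() == pytest.approx(1.0)

    def test_stickiness_stage1_only(self):
        v = np.zeros(2)
        p1 = softmax_policy(v, 1.0, rho=2.0, prev_a1=0, stage=1)
        p2 = softmax_policy(v, 1.0, rho=2.0, prev_a1=0, stage=2)
        assert p1[0] > 0.5
        np.testing.assert_allclose(p2, [0.5, 0.5])


class TestDegeneraciesAndConvergence:
    BASE = {"alpha1": 0.4, "alpha2": 0.6, "elig_lambda": 0.5,
            "beta1": 4.0, "beta2": 4.0, "rho": 0.3}

    def test_w0_equals_pure_model_free(self, hybrid_session):
        nll_h = session_neg_log_likelihood("hybrid", {**self.BASE, "w": 0.0}, hybrid_session)
        nll_mf = session_neg_log_likelihood("mf", self.BASE, hybrid_session)
        assert nll_h == nll_mf

    def test_w1_equals_pure_model_based(self, hybrid_session):
        nll_h = session_neg_log_likelihood("hybrid", {**self.BASE, "w": 1.0}, hybrid_session)
        mb = {k: self.BASE[k] for k in ("alpha2", "beta1", "beta2", "rho")}
        nll_mb = session_neg_log_likelihood("mb", mb, hybrid_session)
        assert nll_h == pytest.approx(nll_mb, abs=1e-10)

    def test_kernel_matches_python_replay(self, hybrid_session):
        params = {"alpha1": 0.3, "alpha2": 0.7, "elig_lambda": 0.9, "w": 0.4,
                  "beta1": 2.5, "beta2": 6.0, "rho": -0.8}
        nll_k = session_neg_log_likelihood("hybrid", params, hybrid_session)
        nll_py = replay_neg_log_likelihood(make_agent("hybrid", params), hybrid_session)
        assert nll_k == pytest.approx(nll_py, abs=1e-9)

    def test_q_converges_to_bernoulli_rate(self):
        """Repeated sampling at alpha=0.1 tracks the true rate (in expectation)."""
        rng = np.random.default_rng(23)
        p_true, alpha = 0.7, 0.1
        finals = []
        for _ in range(50):
            q = 0.0
            for _ in range(500):
                q += alpha * (float(rng.random() < p_true) - q)
            finals.append(q)
        assert np.mean(finals) == pytest.approx(p_true, abs=0.05)
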