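"""Active-inference agent: EFE decomposition, surprise, belief kinetics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from twostep.active_inference import (
    ActiveInferenceAgent,
    AiParams,
    BeliefState,
    adaptation_rate,
    ai_policy,
    bayes_factor_surprise,
    beta_kl,
    efe_final,
    efe_initial,
    habit_bias,
    predictive_outcome_prob,
    predictive_surprise,
    preference_log_prob,
    update_beliefs,
)
from twostep.fitting import make_agent, replay_neg_log_likelihood, session_neg_log_likelihood
from twostep.task import TrialRecord
from twostep.transition import CANDIDATES, TransitionStructure


def uniform_beliefs():
    b = BeliefState.from_prior(0.5)
    assert b.alpha0 == 1.0 and b.beta0 == 1.0
    return b


def kl_quadrature(a1, b1, a2, b2):
    def integrand(x):
        return beta_dist.pdf(x, a1, b1) * (
            beta_dist.logpdf(x, a1, b1) - beta_dist.logpdf(x, a2, b2)
        )
    val, _ = quad(integrand, 0.0, 1.0, limit=200)
    return val


class TestPredictiveAndPreference:
    def test_beta_mean_predictive(self):
        b = uniform_beliefs()
        assert predictive_outcome_prob(b, 1, 0) == 0.5
        b.alpha[0, 0], b.beta[0, 0] = 3.0, 1.0
        assert predictive_outcome_prob(b, 1, 0) == pytest.approx(0.75)

    def test_preference_probabilities(self):
        ln0, ln1 = preference_log_prob(0.0)
        assert ln0 == pytest.approx(math.log(0.5))
        assert ln1 == pytest.approx(math.log(0.5))
        _, ln1 = preference_log_prob(1.0)
        assert math.exp(ln1) == pytest.approx(0.8808, abs=1e-4)
        ln0, ln1 = preference_log_prob(10.0)
        assert math.exp(ln1) == pytest.approx(1.0, abs=1e-8)
        assert math.exp(ln0) + math.exp(ln1) == pytest.approx(1.0)


class TestBetaKl:
    def test_identity_is_zero(self):
        assert beta_kl(1, 1, 1, 1) == 0.0
        assert beta_kl(3.5, 2.2, 3.5, 2.2) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        assert beta_kl(2, 1, 1, 1) == pytest.approx(math.log(2) - 0.5, abs=1e-12)

    def test_agrees_with_quadrature(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            a1, b1, a2, b2 = rng.uniform(0.5, 20, size=4)
            assert beta_kl(a1, b1, a2, b2) == pytest.approx(
                kl_quadrature(a1, b1, a2, b2), abs=1e-6
            )

    def test_nonnegative_and_domain_checked(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a1, b1, a2, b2 = rng.uniform(0.2, 30, size=4)
            assert beta_kl(a1, b1, a2, b2) >= -1e-12
        with pytest.raises(ValueError):
            beta_kl(0.0, 1, 1, 1)


class TestExpectedFreeEnergy:
    def test_flat_preferences_leave_only_information(self):
        b = uniform_beliefs()
        g = efe_final(b, 1, pref_lambda=0.0)
        # extrinsic term is exactly ln 2 for every action at lambda=0
        intrinsic = 0.5 * beta_kl(2, 1, 1, 1) + 0.5 * beta_kl(1, 2, 1, 1)
        np.testing.assert_allclose(g, math.log(2) - intrinsic, atol=1e-12)

    def test_uniform_belief_lambda_one(self):
        g = efe_final(uniform_beliefs(), 1, pref_lambda=1.0)
        assert g[0] == pytest.approx(0.9338, abs=2e-4)

    def test_concentration_reduces_information_value(self):
        b = uniform_beliefs()
        b.alpha[0, 0] = b.beta[0, 0] = 100.0
        g = efe_final(b, 1, pref_lambda=0.0)
        assert g[0] > g[1]  # concentrated pair has less to learn -> higher G

    def test_intrinsic_decreases_with_concentration_at_fixed_mean(self):
        prev = np.inf
        for c in (2.0, 8.0, 32.0, 128.0):
            a, b = 0.6 * c, 0.4 * c
            q = a / (a + b)
            intr = q * beta_kl(a + 1, b, a, b) + (1 - q) * beta_kl(a, b + 1, a, b)
            assert intr < prev
            prev = intr

    def test_initial_stage_sums(self):
        s = TransitionStructure("a0_common_sB", CANDIDATES["a0_common_sB"])
        g2 = np.array([[0.5, 0.5], [1.0, 1.0]])  # sums 1.0 and 2.0
        g1 = efe_initial(g2, s)
        np.testing.assert_allclose(g1, [0.7 * 1.0 + 0.3 * 2.0, 0.3 * 1.0 + 0.7 * 2.0])

    def test_initial_stage_constancy_and_flat_symmetry(self):
        g2 = np.full((2, 2), 0.9)
        s = TransitionStructure("a0_common_sB", CANDIDATES["a0_common_sB"])
        np.testing.assert_allclose(efe_initial(g2, s), [1.8, 1.8])
        flat = TransitionStructure("flat", CANDIDATES["flat"])
        g1 = efe_initial(np.array([[0.1, 0.2], [0.7, 0.4]]), flat)
        assert g1[0] == pytest.approx(g1[1])


class TestHabitAndPolicy:
    def test_first_trial_no_bias(self):
        np.testing.assert_array_equal(habit_bias(2.0, None), [0.0, 0.0])

    def test_kernel_values(self):
        e = habit_bias(1.0, 0)
        assert e[0] == pytest.approx(0.8808, abs=1e-4)
        assert e.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(habit_bias(0.0, 1), [0.5, 0.5])

    def test_zero_kappa_does_not_move_policy(self):
        g = np.array([0.3, 0.9])
        np.testing.assert_allclose(
            ai_policy(g, 3.0, habit_bias(0.0, 0)), ai_policy(g, 3.0), atol=1e-12
        )

    def test_policy_closed_form_and_monotonicity(self):
        p = ai_policy(np.array([0.9, 1.1]), gamma=5.0)
        np.testing.assert_allclose(p, [0.73105858, 0.26894142], atol=1e-8)
        assert p[0] > p[1]  # lower G favoured
        np.testing.assert_allclose(ai_policy(np.array([2.0, -1.0]), 0.0), [0.5, 0.5])

    def test_policy_shift_invariance(self):
        g = np.array([0.2, 1.4])
        p1 = ai_policy(g, 4.0)
        p2 = ai_policy(g + 7.3, 4.0)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert p1.sum() == pytest.approx(1.0)


class TestSurprise:
    def test_predictive_surprise_values(self):
        b = uniform_beliefs()
        assert predictive_surprise(b, 1, 0, 1) == pytest.approx(math.log(2))
        b.alpha[0, 0], b.beta[0, 0] = 9.0, 1.0
        assert predictive_surprise(b, 1, 0, 0) == pytest.approx(-math.log(0.1))
        # more expected outcome -> less surprise
        assert predictive_surprise(b, 1, 0, 1) < predictive_surprise(b, 1, 0, 0)

    def test_bayes_factor_surprise(self):
        b = uniform_beliefs()
        assert bayes_factor_surprise(b, 1, 0, 1) == pytest.approx(1.0)
        b.alpha[0, 0], b.beta[0, 0] = 1.0, 3.0  # predictive p(o=1) = 0.25
        assert bayes_factor_surprise(b, 1, 0, 1) == pytest.approx(2.0)
        assert bayes_factor_surprise(b, 1, 0, 0) > 0

    def test_adaptation_rate(self):
        assert adaptation_rate(0.0, 0.5) == 0.0
        assert adaptation_rate(math.log(2), 0.5) == pytest.approx(0.4094, abs=1e-4)
        assert adaptation_rate(2.0, 0.5) > adaptation_rate(1.0, 0.5)
        assert adaptation_rate(1.0, 0.8) > adaptation_rate(1.0, 0.5)
        with pytest.raises(ValueError):
            adaptation_rate(1.0, 1.0)


def _trial(s2=1, a2=0, o=1, a1=0, t=1):
    return TrialRecord(t=t, a1=a1, s2=s2, transition=1, a2=a2, o=o)


class TestBeliefUpdates:
    def test_conjugate_limit(self):
        """All nu = 0, l = 1 reproduces exact Beta-Bernoulli counting."""
        params = AiParams(nu_ps=0.0, nu_sd=0.0, nu_ud=0.0, learn_rate=1.0)
        b = BeliefState.from_prior(0.5)
        rng = np.random.default_rng(2)
        counts = np.zeros((2, 2, 2))  # state, action, outcome
        for t in range(1, 101):
            s2, a2, o = int(rng.integers(1, 3)), int(rng.integers(2)), int(rng.integers(2))
            counts[s2 - 1, a2, o] += 1
            update_beliefs(b, _trial(s2=s2, a2=a2, o=o, t=t), params)
        np.testing.assert_allclose(b.alpha, 1.0 + counts[:, :, 1])
        np.testing.assert_allclose(b.beta, 1.0 + counts[:, :, 0])

    def test_unsampled_decay_arithmetic(self):
        params = AiParams(variant="full", nu_ud=0.1)
        b = BeliefState.from_prior(0.5)
        b.alpha[1, 1], b.beta[1, 1] = 5.0, 1.0  # pair (s_C, a_B), unsampled below
        update_beliefs(b, _trial(s2=1, a2=0, o=1), params)
        assert b.alpha[1, 1] == pytest.approx(4.6)
        assert b.beta[1, 1] == pytest.approx(1.0)

    def test_unsampled_mean_moves_toward_prior(self):
        params = AiParams(nu_ud=0.2, prior_mean=0.5)
        b = BeliefState.from_prior(0.5)
        b.alpha[1, 1], b.beta[1, 1] = 8.0, 2.0
        means = []
        for t in range(1, 6):
            update_beliefs(b, _trial(t=t), params)
            means.append(b.alpha[1, 1] / (b.alpha[1, 1] + b.beta[1, 1]))
        assert all(m2 < m1 for m1, m2 in zip(means, means[1:]))
        assert means[-1] > 0.5

    def test_variant_pins_its_kinetic(self):
        p = AiParams(variant="nps", nu_ps=0.7, nu_sd=0.3, nu_ud=0.3)
        assert p.effective_nus() == (0.0, 0.3, 0.3)
        p = AiParams(variant="nsd", nu_ps=0.7, nu_sd=0.3, nu_ud=0.3)
        assert p.effective_nus() == (0.7, 0.0, 0.3)
        p = AiParams(variant="nud", nu_ps=0.7, nu_sd=0.3, nu_ud=0.3)
        assert p.effective_nus() == (0.7, 0.3, 0.0)

    def test_prior_pull_flag_restores_full_shrinkage(self):
        base = dict(nu_ps=0.5, nu_sd=0.0, nu_ud=0.0, learn_rate=1.0)
        b1 = BeliefState.from_prior(0.5)
        b1.alpha[0, 0], b1.beta[0, 0] = 9.0, 1.0
        b2 = b1.copy()
        update_beliefs(b1, _trial(o=0), AiParams(**base))
        update_beliefs(b2, _trial(o=0), AiParams(**base, prior_pull=True))
        chi = adaptation_rate(-math.log(0.1), 0.5)
        assert b2.alpha[0, 0] - b1.alpha[0, 0] == pytest.approx(chi * 1.0)


class TestExplorationAndReplay:
    def test_prefers_less_sampled_action(self):
        """Pure information seeker picks the 1-sample action over the 20-sample one."""
        params = AiParams(pref_lambda=0.0, gamma2=5.0)
        agent = ActiveInferenceAgent(params)
        rng = np.random.default_rng(1)
        t = 1
        for _ in range(20):
            agent.learn(_trial(s2=1, a2=0, o=int(rng.integers(2)), t=t)); t += 1
        agent.learn(_trial(s2=1, a2=1, o=1, t=t))
        p = agent.act(2, 1)
        assert p[1] > 0.5

    def test_kernel_matches_python_replay(self, ai_session):
        for model_id, params in [
            ("ai_full", {"pref_lambda": 2.0, "kappa": -0.5, "gamma1": 3.0, "gamma2": 8.0,
                         "prior_mean": 0.3, "learn_rate": 0.7, "nu_ps": 0.6, "nu_sd": 0.2,
                         "nu_ud": 0.4}),
            ("ai_nps", {"pref_lambda": 0.5, "kappa": 1.0, "gamma1": 10.0, "gamma2": 1.0,
                        "prior_mean": 0.7, "learn_rate": 1.5, "nu_sd": 0.3, "nu_ud": 0.1}),
            ("ai_nsd", {"pref_lambda": 5.0, "kappa": 0.0, "gamma1": 0.5, "gamma2": 5.0,
                        "prior_mean": 0.5, "learn_rate": 1.0, "nu_ps": 0.2, "nu_ud": 0.8}),
            ("ai_nud", {"pref_lambda": 9.0, "kappa": 2.0, "gamma1": 7.0, "gamma2": 2.0,
                        "prior_mean": 0.9, "learn_rate": 0.1, "nu_ps": 0.9, "nu_sd": 0.5}),
        ]:
            nll_k = session_neg_log_likelihood(model_id, params, ai_session)
            nll_py = replay_neg_log_likelihood(make_agent(model_id, params), ai_session)
            assert nll_k == pytest.approx(nll_py, abs=1e-9), model_id
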