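import numpy as np
import pytest

from twostep.fitting import make_agent
from twostep.task import TaskConfig, run_session


class UniformAgent:
    """Memoryless agent choosing uniformly at both stages."""

    def act(self, stage, state):
        return np.array([0.5, 0.5])

    def learn(self, trial):
        pass

    def reset(self):
        pass


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig(n_trials=201, seed=7)


@pytest.fixture(scope="session")
def hybrid_session(task_config):
    """201-trial session generated by a mixed hybrid agent."""
    params = {"alpha1": 0.4, "alpha2": 0.6, "elig_lambda": 0.5, "w": 0.6,
              "beta1": 4.0, "beta2": 4.0, "rho": 0.3}
    agent = make_agent("hybrid", params)
    return run_session(agent, task_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def ai_session(task_config):
    """201-trial session generated by a Full-variant active-inference agent."""
    params = {"pref_lambda": 1.5, "kappa": 0.4, "gamma1": 6.0, "gamma2": 6.0,
              "prior_mean": 0.5, "learn_rate": 1.0, "nu_ps": 0.3, "nu_sd": 0.1,
              "nu_ud": 0.2}
    agent = make_agent("ai_full", params)
    return run_session(agent, task_config, np.random.default_rng(13))


@pytest.fixture
def uniform_agent():
    return UniformAgent()
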