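import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from banditbayes import ChoiceModelSpec, EnvironmentConfig, SoftmaxAgent
from banditbayes.task import simulate_agent_session

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def config():
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def bayes_session(config):
    """A 500-trial session generated by a base Bayesian softmax agent."""
    agent = SoftmaxAgent(ChoiceModelSpec("bayes"), {"beta": 5.0}, config)
    return simulate_agent_session(config, agent, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
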