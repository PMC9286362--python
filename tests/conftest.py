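import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aglearn as ag

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def abna_test_set():
    return ag.build_test_set(ag.grammar("ABNA"), seed=7)


@pytest.fixture(scope="session")
def small_study():
    """Two groups x 15 participants, single grammar condition."""
    profiles = {
        "deaf": ag.StrategyProfile(base_logit=float(np.log(0.87 / 0.13))),
        "hearing": ag.StrategyProfile(base_logit=float(np.log(0.97 / 0.03))),
    }
    return ag.simulate_study(profiles, grammars=("ABNA",), seed=5)


@pytest.fixture(scope="session")
def coded_study(small_study):
    from aglearn.coding import annotate_trials, build_consistency_table
    return annotate_trials(build_consistency_table(small_study.trials))
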