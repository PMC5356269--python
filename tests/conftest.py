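import pytest
from hypothesis import HealthCheck, settings

from csfcea.markov import run_all_groups
from csfcea.parameters import default_parameters
from csfcea.sensitivity import run_pipeline

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ps():
    """Packaged base-case parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def outcomes(ps):
    """Base-case lifetime outcomes for the four diagnostic groups."""
    return run_all_groups(ps)


@pytest.fixture(scope="session")
def pipeline(ps):
    """Base-case strategy comparison."""
    return run_pipeline(ps)


# Published per-outcome lifetime values (discounted cost / discounted
# life-years / discounted QALYs / outcome probability), used as frozen
# references wherever printed values are the oracle.
PUBLISHED_OUTCOMES = {
    "TP": {"cost": 298_632.0, "ly": 6.781, "qalys": 2.916, "prob": 0.089},
    "FN": {"cost": 308_586.0, "ly": 6.555, "qalys": 2.660, "prob": 0.038},
    "FP": {"cost": 294_732.0, "ly": 9.157, "qalys": 5.048, "prob": 0.052},
    "TN": {"cost": 283_387.0, "ly": 9.157, "qalys": 5.048, "prob": 0.821},
}


@pytest.fixture(scope="session")
def published_outcomes():
    return PUBLISHED_OUTCOMES
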