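import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tomgrowth.smoothing import loess_fit
from tomgrowth.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (N=324, seed 1)."""
    return generate_cohort(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def default_curve(default_cohort):
    """Span-0.20 quadratic Loess of the default cohort's sum-score."""
    frame = default_cohort.to_frame()
    return loess_fit(frame["age_months"], frame["sum_score"],
                     span=0.20, degree=2, source="sum_score")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
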