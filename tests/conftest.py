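import numpy as np
import pytest
from hypothesis import settings, HealthCheck
from scipy.special import expit

from icuvalid import GeneratorConfig, PredictionSet, generate_cohort
from icuvalid.synthetic import generate_exclusion_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_prediction_set(rng, n=200, slope=1.2, intercept=-0.5, name="model"):
    """Well-calibrated logistic predictions with outcomes drawn from them."""
    x = rng.normal(size=n)
    risk = expit(slope * x + intercept)
    y = (rng.random(n) < risk).astype(int)
    if y.min() == y.max():  # guarantee both classes
        y[0], y[1] = 0, 1
    ids = np.array([f"A{i:05d}" for i in range(n)])
    return PredictionSet.from_risks(name, ids, risk, y)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def preds(rng):
    return make_prediction_set(rng)


@pytest.fixture(scope="session")
def exclusion_fixture():
    return generate_exclusion_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = GeneratorConfig(n=4000, seed=11, noise_sd=0.8)
    return generate_cohort(cfg)
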