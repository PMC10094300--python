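import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kora_cohort():
    """One planted-truth survey-like cohort (binary quality exposure)."""
    from mobipw.synthetic import generate_cohort, make_kora_like_config

    return generate_cohort(make_kora_like_config("quality", seed=42))


@pytest.fixture(scope="session")
def table3_arrays():
    """Outcome/exposure arrays reproducing the printed quality-exposure 2x2
    table: exposed 641 good / 133 bad, unexposed 1285 good / 475 bad."""
    y = np.r_[np.ones(641), np.zeros(133), np.ones(1285), np.zeros(475)]
    e = np.r_[np.ones(774), np.zeros(1760)]
    return y, e


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
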