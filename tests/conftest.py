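import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_population():
    from xgakit import simdata

    return simdata.simulate_population(60, seed=101)


@pytest.fixture(scope="session")
def tiny_truth():
    from xgakit import simdata

    return simdata.simulate_truth(n_loci=16, n_drugs=3, n_influences=2, n_effluxes=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
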