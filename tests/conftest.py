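import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pnhdrift.moran_chain import PoolModel
from pnhdrift.ontogeny import GrowthSchedule

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model() -> PoolModel:
    return PoolModel()


def constant_pool_model(N: int, mu: float) -> PoolModel:
    """Model with a fixed pool size from birth (no ontogenic growth)."""
    sched = GrowthSchedule(n_birth=N, n_adult=N, maturity_age=1e-9)
    return PoolModel(mu=mu, schedule=sched)


@pytest.fixture
def tiny_pool():
    return constant_pool_model(10, 0.0)
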