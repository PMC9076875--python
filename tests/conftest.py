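import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from multidiv import CommunityTable, SimulationConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic chronosequence shared across tests."""
    cfg = SimulationConfig(seed=1)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def toy_table():
    """Tiny count table with known structure."""
    data = pd.DataFrame(
        [[1, 2, 3, 4], [2, 4, 6, 8], [10, 10, 0, 20]],
        index=["p1", "p2", "p3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CommunityTable(data, "bacteria", "count")


@pytest.fixture()
def rng():
    # fresh per test so outcomes do not depend on execution order
    return np.random.default_rng(12345)
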