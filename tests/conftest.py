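import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voltacal as vc

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return vc.PotentialGrid()


@pytest.fixture(scope="session")
def peaks():
    return vc.default_peak_table()


@pytest.fixture(scope="session")
def seed1_pipeline():
    """Full default pipeline at seed 1, shared across tests (81 factorial
    training samples, 10 random test samples, db4/level-3 compression,
    PLS and MLP calibration)."""
    return vc.run_full_pipeline(vc.PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
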