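import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regged.io import ExpressionMatrix
from regged.simulate import SimulationConfig, simulate_compartment_pair

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["PS1", "PS2", "PS3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data=data, compartment_label="glomerulus")


@pytest.fixture
def small_pair():
    """A modest simulated compartment pair with known truth (fast)."""
    config = SimulationConfig(n_probesets=2000, seed=11)
    return simulate_compartment_pair(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
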