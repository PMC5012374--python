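import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellvar.io import ExpressionMatrix
from cellvar.simulate import SimulationConfig, simulate_matrix

settings.register_profile(
    "cellvar",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cellvar")


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Four genes x five cells with hand-picked values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0],
            [0.0, 1.0, 0.0, 3.0, 7.0],
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3", "g4"], ["c1", "c2", "c3", "c4", "c5"], values)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated matrix + truth shared across read-only tests."""
    config = SimulationConfig(n_genes=1500, seed=11, n_highcv=100)
    matrix, truth = simulate_matrix(config)
    return config, matrix, truth
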