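import numpy as np
import pytest

from funcresp import PredatorParams, SimulationConfig, offered_grid


@pytest.fixture(scope="session")
def offered_coarse() -> np.ndarray:
    """Offered-prey grid 1-200 at step 0.5 (the sweep-scale default)."""
    return offered_grid(1.0, 200.0, 0.5)


@pytest.fixture(scope="session")
def disk_params() -> PredatorParams:
    """No-learning predator: constant a=0.1, h=0.1 (plain disk equation)."""
    return PredatorParams.no_learning(0.1, 0.1)


@pytest.fixture(scope="session")
def attack_learner() -> PredatorParams:
    """The canonical attack-learning predator: a0=0.2 -> am=1 at la=0.2,
    handling fixed at 0.1."""
    return PredatorParams.from_values(0.2, 1.0, 0.2, 0.1, 0.1, 0.0)


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig()
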