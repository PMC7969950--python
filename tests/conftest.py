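import numpy as np
import pytest

from catloop import InitialState, ModelParameters, integrate


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def low_alpha_traj():
    """Low-α-catenin inhibition scenario: the biphasic (rise-then-fall) Y case."""
    return integrate(
        ModelParameters(v_Y=0.5),
        InitialState(alpha_cat_init=0.1),
        t_end=10.0,
        n_samples=400,
    )


@pytest.fixture(scope="session")
def high_alpha_traj():
    """High-α-catenin scenario: Y decreases from the start."""
    return integrate(
        ModelParameters(v_Y=0.5),
        InitialState(alpha_cat_init=0.8),
        t_end=10.0,
        n_samples=400,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
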