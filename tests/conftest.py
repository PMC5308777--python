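import numpy as np
import pytest

from phenocoop import ModelParams, Strain, Strategy


@pytest.fixture(scope="session")
def standard_params() -> ModelParams:
    """The model's standard parameter set (N=20, b=1, c=0.3, beta=0.1, theta=0.1, M=50)."""
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_strain(rng: np.random.Generator, k_max: int = 10) -> Strain:
    strategy = Strategy.C if rng.integers(2) else Strategy.D
    return Strain(strategy, int(rng.integers(1, k_max + 1)))
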