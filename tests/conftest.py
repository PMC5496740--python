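import numpy as np
import pytest

from autoflux import KineticParameters, PoolState


@pytest.fixture
def canonical_params() -> KineticParameters:
    """The worked-example parameter set: flux 12, beta 4/h, gamma 2/h."""
    return KineticParameters(influx_J=12.0, beta=4.0, gamma=2.0)


@pytest.fixture
def canonical_pools() -> PoolState:
    """Steady state of the worked-example parameters."""
    return PoolState(ap=3.0, al=6.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def sample_params(rng: np.random.Generator, n: int) -> list[KineticParameters]:
    """Random positive parameter sets spanning a few orders of magnitude."""
    js = rng.uniform(0.5, 50.0, n)
    betas = np.exp(rng.uniform(np.log(0.05), np.log(20.0), n))
    gammas = np.exp(rng.uniform(np.log(0.05), np.log(20.0), n))
    return [KineticParameters(j, b, g) for j, b, g in zip(js, betas, gammas)]
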