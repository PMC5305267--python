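import numpy as np
import pytest

from polartension import ModelParams, make_disk
from polartension.solver import SolverConfig


@pytest.fixture(scope="session")
def params_small():
    """Coarse grid for fast unit tests (interface widened to stay resolved)."""
    return ModelParams(N=64, eps=1.5)


@pytest.fixture(scope="session")
def params_desk():
    """Production-resolution desk-scale configuration used by the
    calibrated experiments (N=96, dt=0.02)."""
    return ModelParams(N=96, dt=0.02)


@pytest.fixture(scope="session")
def disk_small(params_small):
    return make_disk(params_small)


@pytest.fixture(scope="session")
def disk_desk(params_desk):
    return make_disk(params_desk)


@pytest.fixture(scope="session")
def cfg_desk(params_desk):
    return SolverConfig(dt=params_desk.dt, t_end=0.0, snapshot_every=200)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
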