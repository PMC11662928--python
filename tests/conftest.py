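import numpy as np
import pytest

from npkinetics.lattice import (
    LatticeConfig,
    Protocol,
    Segment,
    reference_params,
)
from npkinetics.polymer import ExtensionModel, FJCParams


@pytest.fixture(scope="session")
def params():
    return reference_params()


@pytest.fixture(scope="session")
def fjc():
    return FJCParams()


@pytest.fixture(scope="session")
def ext_model():
    return ExtensionModel()


@pytest.fixture(scope="session")
def kBT(fjc):
    return fjc.kBT


@pytest.fixture
def small_config():
    """20-site trimer lattice (1 knt) for fast stochastic tests."""
    return LatticeConfig(n_nt=1000)


@pytest.fixture
def standard_protocol():
    return Protocol(
        force=30.0,
        schedule=(Segment(100.0, 30.0), Segment(150.0, 0.0)),
        seed=0,
    )


def make_protocol(force=30.0, conc=30.0, incubation=100.0, washout=150.0,
                  seed=0, noise_sd=2.0):
    schedule = [Segment(incubation, conc)]
    if washout > 0:
        schedule.append(Segment(washout, 0.0))
    return Protocol(force=force, schedule=tuple(schedule), seed=seed,
                    noise_sd=noise_sd)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
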