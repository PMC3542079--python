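import warnings

import numpy as np
import pytest

import lifediff as ld

warnings.filterwarnings("ignore", message="dropped .* windows")

FRAME_DT = 1.0 / 30.0


@pytest.fixture(scope="session")
def demo_1state():
    return ld.make_fixture("demo_1state")


@pytest.fixture(scope="session")
def demo_static():
    return ld.make_fixture("demo_2state_static")


@pytest.fixture(scope="session")
def demo_switching():
    return ld.make_fixture("demo_2state_switching")


@pytest.fixture(scope="session")
def pten3():
    return ld.make_fixture("pten3_nonpolar")


@pytest.fixture(scope="session")
def switching_ensemble(demo_switching):
    """1000 tracks of the two-state switching model (standard protocol)."""
    return ld.simulate_ensemble(demo_switching, 1000, seed=0)


@pytest.fixture(scope="session")
def static_ensemble(demo_static):
    return ld.simulate_ensemble(demo_static, 1000, seed=0)


@pytest.fixture(scope="session")
def switching_mixture_fit(switching_ensemble):
    return ld.fit_displacement_mixture(
        switching_ensemble.displacements(), 2, eps=0.04, dt=FRAME_DT)


@pytest.fixture(scope="session")
def switching_profiles(switching_ensemble, switching_mixture_fit):
    return ld.windowed_fractions(switching_ensemble,
                                 switching_mixture_fit.D, eps=0.04)
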