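import warnings

import numpy as np
import pytest

from photontau import IRFModel, PhotonTrace, SimConfig, default_acquisition, simulate_trace


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """The benchmark configurations legitimately strain the no-wraparound
    guidance (25 ns period with a 10 ns species); silence those advisory
    warnings so test output stays readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*wrap-around.*")
        warnings.filterwarnings("ignore", message=".*no-wraparound.*")
        yield


@pytest.fixture(scope="session")
def acquisition():
    """(pulse_period, IRFModel) of the default 40 MHz setup."""
    return default_acquisition()


@pytest.fixture(scope="session")
def irf(acquisition):
    return acquisition[1]


@pytest.fixture(scope="session")
def two_species_trace(acquisition):
    """The canonical two-species benchmark: 1 and 10 ns, 50:50, 3,000 photons."""
    period, irf = acquisition
    cfg = SimConfig(
        lifetimes=(1.0, 10.0), fractions=(0.5, 0.5), n_photons=3000,
        irf=irf, pulse_period=period, seed=73,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace, truth = simulate_trace(cfg)
    return trace, truth


@pytest.fixture()
def tiny_trace():
    return PhotonTrace(microtimes=np.array([0.4, 2.1, 7.3]), pulse_period=25.0)
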