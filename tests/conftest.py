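import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from sdvrc.core import Environment, SdvrcParams
from sdvrc.fitting import ecoli_reference_calibration, fit_sdvrc, load_ecoli_probes


@pytest.fixture(scope="session")
def env():
    return Environment()


@pytest.fixture(scope="session")
def probe_fit():
    """Curve fitted to the packaged 31-probe literature panel."""
    return fit_sdvrc(load_ecoli_probes())


@pytest.fixture(scope="session")
def ref_cal():
    """The recovered published cytoplasm calibration."""
    return ecoli_reference_calibration()


@pytest.fixture(scope="session")
def nominal_params():
    """The published (rounded) cytoplasm parameter triple."""
    return SdvrcParams(0.51, 42.0, 0.53)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
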