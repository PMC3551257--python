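import numpy as np
import pytest

from hepatosim import experiments
from hepatosim.cell_kinetics import EnzymeProfile, basal_state
from hepatosim.injury import InjuryParameters
from hepatosim.sinusoid_transport import SinusoidGeometry


@pytest.fixture(scope="session")
def profile() -> EnzymeProfile:
    return EnzymeProfile()


@pytest.fixture(scope="session")
def geometry() -> SinusoidGeometry:
    return SinusoidGeometry()


@pytest.fixture(scope="session")
def calibrated():
    """LC50-calibrated injury parameters + profile (shared; ~5 s once)."""
    return experiments.calibrate_injury(4000.0)


@pytest.fixture()
def basal(profile) -> np.ndarray:
    return basal_state(profile)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def no_injury() -> InjuryParameters:
    """Necrosis disabled (infinite threshold is disallowed by validation,
    so use a threshold far above any reachable H2O2)."""
    return InjuryParameters(h2o2_crit=1e12, hazard_scale=0.0)
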