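import numpy as np
import pytest

from lumistraddle import SternVolmerLaw, TimingConfig


@pytest.fixture(scope="session")
def sensor() -> SternVolmerLaw:
    """PtTFPP-like O2 sensor: 62 us unquenched, 22 us at air saturation."""
    return SternVolmerLaw.from_endpoints(62.0, 22.0)


@pytest.fixture(scope="session")
def timing80() -> TimingConfig:
    """80 us pulse with complete decay capture between frames."""
    return TimingConfig(pulse_length=80.0)


@pytest.fixture(scope="session")
def timing80_finite() -> TimingConfig:
    """80 us pulse, 2 ms exposure (finite window for quadrature/noise)."""
    return TimingConfig(pulse_length=80.0, exposure=2000.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
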