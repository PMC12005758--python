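import numpy as np
import pytest

from magassembly.params import (
    ConfigBundle,
    MagnetSpec,
    NanoparticleSpec,
    SimulationParameters,
    WellGeometry,
)


@pytest.fixture
def np_spec():
    return NanoparticleSpec()


@pytest.fixture
def magnet():
    return MagnetSpec()


@pytest.fixture
def well():
    return WellGeometry()


@pytest.fixture
def params():
    return SimulationParameters()


def make_bundle(**overrides) -> ConfigBundle:
    """Bundle with Table-default physics and optional scalar overrides."""
    return ConfigBundle(
        SimulationParameters(**overrides),
        NanoparticleSpec(),
        MagnetSpec(),
        WellGeometry(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
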