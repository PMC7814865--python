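import pytest

from mvdry import (HeatTransferParams, MassTransferParams, VialGeometry,
                   load_builtin_cycle)
from mvdry.config import lyo_default_heat_params, mvd_default_heat_params
from mvdry.simulator import Formulation


@pytest.fixture(scope="session")
def geometry():
    return VialGeometry()


@pytest.fixture(scope="session")
def mass_params():
    return MassTransferParams()


@pytest.fixture(scope="session")
def formulation():
    return Formulation()


@pytest.fixture(scope="session")
def mvd_cycle():
    return load_builtin_cycle("mvd_full")


@pytest.fixture(scope="session")
def lyo_cycle():
    return load_builtin_cycle("lyo_benchmark")


@pytest.fixture(scope="session")
def mvd_heat():
    return mvd_default_heat_params()


@pytest.fixture(scope="session")
def lyo_heat():
    return lyo_default_heat_params()


@pytest.fixture
def zero_heat():
    """All conventional heat sources switched off."""
    return HeatTransferParams(Kc=0.0, Kg=0.0, shelf_emissivity=0.0,
                              vial_top_emissivity=0.0)
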