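import pytest

from tfantenna.binding_model import EnergyModelParams
from tfantenna.antenna_kinetics import AntennaPhysical


@pytest.fixture
def params():
    """Default fitted energy-model parameters."""
    return EnergyModelParams()


@pytest.fixture
def zeroed_params():
    """All free energies zeroed: every site has dG = 0, weight 1."""
    return EnergyModelParams(
        dg_consensus_core=0.0, dg_degenerate_at=0.0, dg_cp=0.0, dg_elec0=0.0
    )


@pytest.fixture
def phys():
    return AntennaPhysical()
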