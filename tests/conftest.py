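import numpy as np
import pytest

from coroflow.geometry import synth_stenosis_geometry
from coroflow.solver import FlowModel, FluidProperties


@pytest.fixture(scope="session")
def analogue():
    return FluidProperties.analogue()


@pytest.fixture(scope="session")
def blood():
    return FluidProperties.blood()


@pytest.fixture(scope="session")
def tube():
    """Straight tube, R = 1.5 mm, L = 80 mm — the Poiseuille reference case."""
    return synth_stenosis_geometry(ref_diameter_mm=3.0, length_mm=80.0,
                                   percent_ds=0.0)


@pytest.fixture(scope="session")
def tube_model(tube, analogue):
    """Shared solver instance for the straight tube (cache reused across tests)."""
    return FlowModel(tube, analogue)


@pytest.fixture(scope="session")
def sten60():
    return synth_stenosis_geometry(3.0, 80.0, 60.0)


@pytest.fixture(scope="session")
def sten60_model(sten60, analogue):
    return FlowModel(sten60, analogue)


@pytest.fixture(scope="session")
def sten72():
    return synth_stenosis_geometry(3.0, 80.0, 72.0)


@pytest.fixture(scope="session")
def sten72_model(sten72, analogue):
    return FlowModel(sten72, analogue)


def poiseuille_dp_mmHg(fluid, radius_m, length_m, q_mL_min):
    """Closed-form fully developed laminar pressure drop, the solver oracle."""
    q = q_mL_min * 1e-6 / 60.0
    return 8.0 * fluid.viscosity_Pa_s * length_m * q / (
        np.pi * radius_m**4) / 133.322
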