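import numpy as np
import pytest

import rhoct
from rhoct.physics import MaterialPoint, mass_attenuation, mu_over_rho_to_hu


@pytest.fixture(scope="session")
def water():
    return rhoct.WaterReference()


@pytest.fixture(scope="session")
def inversion():
    return rhoct.LehmannInversion().fit()


@pytest.fixture(scope="session")
def gammex():
    return rhoct.builtin_phantom("gammex467")


@pytest.fixture(scope="session")
def catphan():
    return rhoct.builtin_phantom("catphan504")


@pytest.fixture(scope="session")
def gammex_noiseless_pair(gammex):
    """Small-grid noiseless Gammex VMI pair shared across tests."""
    return rhoct.generate_vmi_pair(gammex, noise=None, n_inplane=128)


def forward_hu_pair(rho_rel, z_eff, water, energies=(50.0, 200.0)):
    """Noiseless HU pair of a homogeneous material via the forward model."""
    pt = MaterialPoint.from_relative(rho_rel, z_eff)
    return [
        mu_over_rho_to_hu(mass_attenuation(pt, e), e, water) for e in energies
    ]
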