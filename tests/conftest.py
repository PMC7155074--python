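import pytest
from hypothesis import settings

from isojump import fixtures as fx

# property tests are derandomized; keep runs stateless (no example database)
settings.register_profile("stateless", database=None, deadline=None)
settings.load_profile("stateless")
from isojump.exciton import NN_COUPLING_EMPIRICAL, SiteDipoleParams


@pytest.fixture(scope="session")
def structure():
    """Canonical 23-residue three-stranded sheet."""
    return fx.canonical_structure()


@pytest.fixture(scope="session")
def calibrated_model():
    """Site-energy model calibrated to the single-label band maxima."""
    return fx.calibrated_site_model()


@pytest.fixture(scope="session")
def dipole_params():
    return SiteDipoleParams()


@pytest.fixture(scope="session")
def nn_coupling():
    return NN_COUPLING_EMPIRICAL


@pytest.fixture(scope="session")
def catalog():
    return {f.name: f for f in fx.variant_catalog()}
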