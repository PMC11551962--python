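import pytest
from hypothesis import settings

from selectnet import io

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def abfe_table():
    """Packaged two-host absolute binding free energies, keyed by
    (receptor, ligand)."""
    return io.fixtures("sampl8_abfe")


@pytest.fixture(scope="session")
def rhfe_edges():
    return io.fixtures("sampl8_rhfe")


@pytest.fixture(scope="session")
def rbfe_edges():
    return io.fixtures("sampl8_rbfe")


@pytest.fixture(scope="session")
def rsfe_edges():
    return io.fixtures("sampl8_rsfe")


@pytest.fixture(scope="session")
def two_host_network():
    """All 20 RBFE edges + all 5 RHFE hops, anchored at TEMOA·G1."""
    return io.sampl8_complex_network()


@pytest.fixture(scope="session")
def swap_network():
    """The 10-edge swap network anchored at G1's direct hopping value."""
    return io.sampl8_selectivity_network()
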