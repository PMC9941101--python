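import numpy as np
import pytest

from ribomod import RnaReference, SiteCatalog, ModificationSite
from ribomod import fixtures


@pytest.fixture(scope="session")
def refs():
    return fixtures.demo_references()


@pytest.fixture(scope="session")
def nm_catalog():
    return fixtures.demo_nm_catalog()


@pytest.fixture(scope="session")
def psi_catalog():
    return fixtures.demo_psi_catalog()


@pytest.fixture(scope="session")
def small_ref():
    """A fixed 40-nt molecule with a uridine at position 20."""
    rng = np.random.default_rng(42)
    seq = rng.choice(list("ACG"), size=40)
    seq[19] = "U"
    return RnaReference("mini", "".join(seq))


@pytest.fixture(scope="session")
def small_nm_catalog(small_ref):
    site = ModificationSite("mini", 20, small_ref.residue(20), "Nm", ("SNORD90",))
    return SiteCatalog.from_sites([site], refs={"mini": small_ref})
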