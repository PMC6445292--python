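import numpy as np
import pytest

from allosite import synthetic_data as sd
from allosite.site_definition import define_binding_site


@pytest.fixture(scope="session")
def anchors():
    spec = sd.GeneratorSpec(seed=0)
    return sd.build_anchors(spec)


@pytest.fixture(scope="session")
def reference_complex():
    return sd.reference_complex()


@pytest.fixture(scope="session")
def site_selection(reference_complex):
    return define_binding_site(reference_complex, sd.LIGAND_RESNAME, 4.5)


@pytest.fixture(scope="session")
def small_suite():
    """Reduced-length four-condition suite shared across test modules."""
    return sd.generate_condition_suite(n_frames=120, seed=20210)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
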