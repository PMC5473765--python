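import numpy as np
import pytest

from retrochrono import synth


@pytest.fixture(scope="session")
def copia_spec():
    return synth.FamilySpec(
        family_id="copA",
        superfamily="copia",
        ltr_length=400,
        internal_length=2500,
        domain_order=synth.COPIA_ORDER,
        copy_number=3,
        age_distribution=1.0e6,
    )


@pytest.fixture(scope="session")
def small_genome(copia_spec):
    """50 kb background with three aged copia copies."""
    return synth.build_genome([copia_spec], 50_000, seed=2)


@pytest.fixture(scope="session")
def fresh_genome():
    """Age-0 single element: exact LTRs and verbatim planted domains."""
    spec = synth.FamilySpec(
        family_id="fresh",
        superfamily="gypsy",
        ltr_length=300,
        internal_length=2200,
        domain_order=synth.GYPSY_ORDER,
        copy_number=1,
        age_distribution=0.0,
    )
    return synth.build_genome([spec], 30_000, seed=7)


@pytest.fixture(scope="session")
def random_50kb():
    return synth.build_genome([], 50_000, seed=13).sequence


def pytest_configure(config):
    np.seterr(all="raise")
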