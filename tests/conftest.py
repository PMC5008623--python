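import pytest

from plasmidbreaks import IncubationSetup, FractionTriple


@pytest.fixture(scope="session")
def setup():
    """The reference incubation: 15 MBq 99mTc, 24 h, 200 ng of 2686 bp plasmid."""
    return IncubationSetup()


@pytest.fixture(scope="session")
def decay(setup):
    return setup.decay_result()


@pytest.fixture(scope="session")
def d_ref(decay):
    """Decays per plasmid for the reference incubation (~6.37)."""
    return decay.decays_per_plasmid


@pytest.fixture
def ib_triple():
    """Mean fractions for the tightly bound pyrene complex: SC 13, OC 64, L 23 %."""
    return FractionTriple(f_sc=0.13, f_oc=0.64, f_l=0.23)
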