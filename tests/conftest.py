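import pytest

from hdrkit.donor import derive_signature_pattern
from hdrkit.simulate import (
    SimulationConfig,
    default_guides,
    make_reference,
    published_donor,
)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture()
def locus(config):
    # function-scoped: some tests mutate the contig via apply_variant
    return make_reference(config)


@pytest.fixture()
def guides(locus):
    return default_guides(locus)


@pytest.fixture()
def donor(locus, guides):
    """The four-shield donor as published for this locus."""
    return published_donor(locus, guides)


@pytest.fixture()
def pattern(donor):
    return derive_signature_pattern(donor)
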