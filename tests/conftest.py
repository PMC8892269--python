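import pytest

from tds import synthio


@pytest.fixture(scope="session")
def default_config():
    return synthio.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def locus(default_config):
    """(genome, [spliced, full]) of the default synthetic locus."""
    return synthio.make_synthetic_locus(default_config)
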