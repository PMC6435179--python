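import pytest

from satarray import standins


@pytest.fixture(scope="session")
def monomers():
    """Stand-in monomer consensuses (deterministic, seed 0)."""
    return standins.standin_monomers(0)


@pytest.fixture(scope="session")
def fragment_sets():
    """Stand-in fragment sets (deterministic, seed 0)."""
    return standins.standin_fragment_sets(0)
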