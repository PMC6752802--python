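import pytest

from fawkit import markers, synthdata


@pytest.fixture(scope="session")
def refs() -> markers.ReferenceSet:
    """Deterministic synthetic reference set shared across tests."""
    return synthdata.make_references(seed=11)


@pytest.fixture(scope="session")
def bundled_refs() -> markers.ReferenceSet:
    """The reference set shipped as package data."""
    return markers.load_default_references()
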