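import pytest

from htspot import DispersionModel, builtin_panel, reference_registry


@pytest.fixture(scope="session")
def model() -> DispersionModel:
    return DispersionModel()


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def registry():
    return reference_registry()


@pytest.fixture(scope="session")
def marker_by_name(panel):
    return {m.name: m for m in panel}
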