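import pytest

from fntqivive import DosingRegimen, default_model, load_defaults


@pytest.fixture(scope="session")
def rat_defaults():
    return load_defaults("rat")


@pytest.fixture(scope="session")
def human_defaults():
    return load_defaults("human")


@pytest.fixture(scope="session")
def rat_model():
    return default_model("rat")


@pytest.fixture(scope="session")
def human_model():
    return default_model("human")


@pytest.fixture
def oral_regimen():
    return DosingRegimen(route="oral", dose=15.0)
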