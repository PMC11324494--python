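import pytest
from hypothesis import settings

import aortaflow as af

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inputs():
    return af.load_inputs()


@pytest.fixture(scope="session")
def printed():
    return af.load_printed()


@pytest.fixture(scope="session")
def base60(inputs):
    return af.column_params(inputs, "base60")


@pytest.fixture(scope="session")
def base80(inputs):
    return af.column_params(inputs, "base80")
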