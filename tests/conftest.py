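import pytest
from hypothesis import settings

from glyproform import make_c8_fixture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def c8():
    """The packaged C8 ground-truth fixture (default backbone, default
    minor-glycoform point value)."""
    return make_c8_fixture()
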