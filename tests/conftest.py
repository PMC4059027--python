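import pytest

from edsim import builtin_profile


@pytest.fixture(scope="session")
def national_cfg():
    return builtin_profile("national")


@pytest.fixture(scope="session")
def academic_cfg():
    return builtin_profile("academic")
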