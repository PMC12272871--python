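import pytest

from termini import default_template


@pytest.fixture(scope="session")
def t7_template():
    return default_template("T7")


@pytest.fixture(scope="session")
def cd_template():
    return default_template("CD23823")
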