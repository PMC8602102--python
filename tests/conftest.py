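import pytest

from fuzzycell import load_metabolism, load_tcd4


@pytest.fixture(scope="session")
def metabolism():
    return load_metabolism()


@pytest.fixture(scope="session")
def tcd4():
    return load_tcd4()
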