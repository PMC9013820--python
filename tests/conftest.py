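import pytest

from biopsim.rng import UniformSource


@pytest.fixture
def source():
    """Fresh deterministic uniform source."""
    return UniformSource(12345)


@pytest.fixture
def make_source():
    return lambda seed: UniformSource(seed)
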