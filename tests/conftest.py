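import numpy as np
import pytest
from hypothesis import settings

from securelr import Channel, FixedPointFormat, LiveSource, ProtocolContext

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fmt64():
    """Reference operating point: a=12 fractional, b=15 integer bits, λ=64."""
    return FixedPointFormat(12, 15, 64)


@pytest.fixture
def fmt8():
    """Tiny ring for exhaustive checks."""
    return FixedPointFormat(2, 2, 8)


@pytest.fixture
def fmt16():
    return FixedPointFormat(4, 4, 16)


def make_ctx(fmt: FixedPointFormat, seed: int = 0) -> ProtocolContext:
    """Fresh protocol session with an on-demand TI and a clean channel."""
    return ProtocolContext(fmt, LiveSource(seed), Channel())


@pytest.fixture
def ctx64(fmt64):
    return make_ctx(fmt64)


@pytest.fixture
def ctx8(fmt8):
    return make_ctx(fmt8)
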