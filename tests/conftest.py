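import pytest

from gcn4sim.layout import (
    DEFAULT_LAYOUT,
    DEREPRESSING,
    DEREPRESSING_MODEL2,
    REPRESSING,
    REPRESSING_MODEL2,
)


@pytest.fixture
def layout():
    return DEFAULT_LAYOUT


@pytest.fixture
def repressing():
    return REPRESSING.rates


@pytest.fixture
def derepressing():
    return DEREPRESSING.rates


@pytest.fixture
def repressing_m2():
    return REPRESSING_MODEL2.rates


@pytest.fixture
def derepressing_m2():
    return DEREPRESSING_MODEL2.rates
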