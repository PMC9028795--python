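import pytest

from leafoptics import default_parameters, synthetic_refractive_index


@pytest.fixture(scope="session")
def coeffs():
    return default_parameters()


@pytest.fixture(scope="session")
def grid(coeffs):
    return coeffs.grid


@pytest.fixture(scope="session")
def m_la(grid):
    return synthetic_refractive_index(grid)
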