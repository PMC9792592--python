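import numpy as np
import pytest

from planarchip import (
    SyntheticSPResponse,
    default_chip,
    find_operating_wavelengths,
    scalar_otf,
    select_operating_wavelength,
)


@pytest.fixture(scope="session")
def chip():
    """The default 40-layer Si3N4/SiO2 differentiator chip on glass."""
    return default_chip()


@pytest.fixture(scope="session")
def chip_scan(chip):
    """Dominant-order classification of the chip over 600-700 nm (full table)."""
    return find_operating_wavelengths(chip, np.arange(600.0, 700.01, 0.5), full=True)


@pytest.fixture(scope="session")
def lambda2(chip_scan):
    """The chip's second-order operating wavelength (strongest theta^2 response)."""
    lam = select_operating_wavelength(
        chip_scan[chip_scan["dominant_order"].notna()], 2)
    assert lam is not None
    return lam


@pytest.fixture(scope="session")
def dc2_response():
    """Synthetic s/p pair with a pure quadratic difference, dC2 = 1."""
    return SyntheticSPResponse({2: 1.0})


@pytest.fixture(scope="session")
def dc4_response():
    """Synthetic s/p pair with a pure quartic difference, dC4 = 2."""
    return SyntheticSPResponse({4: 2.0})


@pytest.fixture(scope="session")
def dc2_otf(dc2_response):
    return scalar_otf(dc2_response, 643.0, na=0.45, n_samples=257)


@pytest.fixture(scope="session")
def dc4_otf(dc4_response):
    return scalar_otf(dc4_response, 638.0, na=0.45, n_samples=257)
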