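import numpy as np
import pytest

from ratchetkin import (
    MMCoefficients,
    PHI29_COEFFS,
    PHI29_RATES,
    RatchetRates,
)


@pytest.fixture(scope="session")
def coeffs() -> MMCoefficients:
    """Published best-fit Michaelis-Menten coefficients."""
    return PHI29_COEFFS


@pytest.fixture(scope="session")
def rates() -> RatchetRates:
    """Published ratchet cycle rates."""
    return PHI29_RATES


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
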