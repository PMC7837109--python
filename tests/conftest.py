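import numpy as np
import pytest

from itsreg.datasets import reference_fit, reference_interruption


@pytest.fixture(scope="session")
def ref_coeffs():
    """Reference national all-attendance linear fit."""
    return reference_fit()


@pytest.fixture(scope="session")
def spec():
    """Default interruption window (weeks 63-66, reference week 67)."""
    return reference_interruption()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230417)
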