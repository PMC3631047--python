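import numpy as np
import pytest

from efgrade import reading_study


@pytest.fixture(scope="session")
def study():
    """The bundled two-radiologist, two-occasion, 32-patient score table."""
    return reading_study()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
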