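import numpy as np
import pytest

from ddscreen.assay import gpr126_screening_assay
from ddscreen.simulate import AmplitudeModel, ChannelAmplitudeModel


@pytest.fixture(scope="session")
def assay():
    return gpr126_screening_assay()


@pytest.fixture(scope="session")
def separated_model():
    """Amplitude model with huge cluster separation and no rain."""
    ch = ChannelAmplitudeModel(1000.0, 100.0, 8000.0, 100.0, rain_fraction=0.0)
    return AmplitudeModel(fam=ch, hex=ch)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
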