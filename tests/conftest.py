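import numpy as np
import pytest

from rdmpart.pipeline import SCALED_COMPOSITION
from rdmpart.rdm_core import StimulusSet


@pytest.fixture(scope="session")
def stimuli24() -> StimulusSet:
    """Quarter-scale stimulus set: 24 images in the 6-category proportions."""
    return StimulusSet.from_composition(SCALED_COMPOSITION)


@pytest.fixture(scope="session")
def stimuli92() -> StimulusSet:
    """The canonical 92-image composition."""
    return StimulusSet.from_composition()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
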