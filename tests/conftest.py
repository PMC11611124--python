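import numpy as np
import pytest

from fmsync.preprocess import BeatTimes


@pytest.fixture
def const_maternal_600s() -> BeatTimes:
    """Exactly periodic maternal train at 60 bpm for 10 minutes."""
    return BeatTimes(np.arange(601.0), role="maternal", subject_id="M1")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
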