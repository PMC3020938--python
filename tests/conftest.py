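import numpy as np
import pytest

from figtext.ocr import FixtureRecognizer
from figtext.synthetic import make_dataset


@pytest.fixture(scope="session")
def fixture_engine():
    """Shared glyph-atlas recognizer (atlas construction is the slow part)."""
    return FixtureRecognizer()


@pytest.fixture(scope="session")
def easy_dataset():
    """Small easy-profile dataset shared by integration tests."""
    return make_dataset(8, "easy", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
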