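import numpy as np
import pytest
from hypothesis import settings

from dualcassette.events import CassetteEvent

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def event():
    """Plus-strand worked example used throughout the docs."""
    return CassetteEvent(
        event_id="ev1",
        chrom="chr1",
        strand="+",
        c1=(100, 200),
        a1=(301, 360),
        a2=(461, 520),
        c2=(621, 900),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
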