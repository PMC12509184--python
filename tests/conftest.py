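import numpy as np
import pytest

from qsuppress import (
    SequenceSpec,
    build_w5,
    default_offset_grid,
    sculpting_profile,
)


@pytest.fixture(scope="session")
def w5_1800_profile():
    """Idealized W5 double-echo profile, 25 Hz grid over +-2500 Hz, raw."""
    train = build_w5(1800.0)
    return sculpting_profile(SequenceSpec(train), default_offset_grid())


@pytest.fixture(scope="session")
def w5_1800_normalized(w5_1800_profile):
    return w5_1800_profile.normalized()


@pytest.fixture(scope="session")
def w5_2400_normalized():
    train = build_w5(2400.0)
    prof = sculpting_profile(
        SequenceSpec(train), default_offset_grid(span=3000.0)
    )
    return prof.normalized()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
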