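import numpy as np
import pytest

from mrfmoco.sequence import SequenceParams, default_flip_angles, sinc_slice_profile


@pytest.fixture(scope="session")
def short_seq():
    """150-TR inversion-prepared sequence with the default flip-angle train."""
    return SequenceParams(flip_angles=default_flip_angles(150))


@pytest.fixture(scope="session")
def tiny_profile():
    """5-point slice profile (fast stand-in for the 50-point default)."""
    return sinc_slice_profile(5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
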