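import numpy as np
import pytest

from nfloop import SessionConfig, VirtualSubjectProfile


@pytest.fixture
def config():
    return SessionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def responder_profile():
    return VirtualSubjectProfile()


@pytest.fixture
def non_respondent_profile():
    """Subject with zero left-asymmetry gain: NF engages the right side
    instead, so asymmetry drops during NF and never reaches the threshold."""
    return VirtualSubjectProfile(
        subject_id="null01", responder_gain=0.0, right_gain=0.4)
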