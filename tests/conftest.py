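import numpy as np
import pytest

from wapmelt.watermass import EndMemberSet


@pytest.fixture
def endmembers() -> EndMemberSet:
    """A well-conditioned WAP-like end-member triangle (illustrative)."""
    return EndMemberSet(s_sim=6.0, s_met=0.0, s_ow=34.73,
                        d18o_sim=1.9, d18o_met=-16.0, d18o_ow=-0.14)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
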