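import numpy as np
import pytest

from trflpkit import DetectionConfig, Peak, Profile


@pytest.fixture
def detection50():
    return DetectionConfig(pdt=50.0)


@pytest.fixture
def detection100():
    return DetectionConfig(pdt=100.0)


def make_profile(pid, sizes, heights=None, areas=None, sample=None):
    heights = heights if heights is not None else [100.0] * len(sizes)
    if areas is None:
        peaks = [Peak(s, h) for s, h in zip(sizes, heights)]
    else:
        peaks = [Peak(s, h, a) for s, h, a in zip(sizes, heights, areas)]
    return Profile(
        profile_id=pid,
        sample_id=sample or pid,
        peaks=tuple(sorted(peaks, key=lambda p: p.size)),
    )


@pytest.fixture
def duplicate_pair():
    """A loading-duplicate-like pair sharing three fragments plus one unique."""
    a = make_profile("dup|L1", [100.0, 150.2, 300.5], [800, 400, 200], sample="dup")
    b = make_profile("dup|L2", [100.3, 150.1, 300.7, 420.0], [900, 380, 210, 90], sample="dup")
    return a, b


@pytest.fixture
def rng():
    return np.random.default_rng(20140360)
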