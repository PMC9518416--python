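import numpy as np
import pytest

from drowsinet.synth import SubjectProfile


@pytest.fixture
def steady_profile():
    """Single-level profile with deterministic (noise-free) RR modulation."""
    return SubjectProfile("s1", ((300.0, 1),), noise_sd_ms=0.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
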