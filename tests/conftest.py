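import numpy as np
import pytest

from pcgkit import SynthSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20231105)


@pytest.fixture(scope="session")
def clean_record():
    """A jitter-free normal recording with 6 closable cycles at 75 bpm."""
    spec = SynthSpec(duration_s=6 * 0.8 + 0.3, heart_rate_bpm=75.0, jitter_pct=0.0, seed=7)
    return generate(spec)
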