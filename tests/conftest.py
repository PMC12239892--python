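import numpy as np
import pytest

from subscalp_eeg.synthdata import make_head_layout


@pytest.fixture(scope="session")
def layout4():
    """Full-coverage layout: 25 scalp + 28 subscalp + 6 intracranial."""
    return make_head_layout(4, 6, seed=1)


@pytest.fixture(scope="session")
def layout1():
    """Minimal implant: one trident, no intracranial contacts."""
    return make_head_layout(1, 0, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
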