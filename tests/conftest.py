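import numpy as np
import pytest

import finchcall as fc


@pytest.fixture(scope="session")
def tutor():
    """Rendered ABAB tutor motif and its ground-truth syllable events."""
    clip, truth = fc.render_tutor_audio(sample_rate=44100, seed=0)
    return clip, truth


@pytest.fixture(scope="session")
def small_session():
    """One short simulated session: (box, backpack, ground truth)."""
    cfg = fc.SessionSimConfig(session_dur_s=60.0, call_base_rate_hz=0.8, seed=11)
    return fc.simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
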