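import numpy as np
import pytest

import ripplecoord as rc


@pytest.fixture(scope="session")
def default_recording():
    """A 540 s synthetic session (SWS/REM schedule) with ground truth."""
    cfg = rc.SynthConfig(duration_s=540.0, seed=11)
    return rc.generate_recording(cfg)


@pytest.fixture(scope="session")
def scored_states(default_recording):
    rec, _ = default_recording
    return rc.score_sleep_states(rec.lfp_ca1, rec.fs_ca1, rec.immobility)


@pytest.fixture(scope="session")
def detected_ripples(default_recording, scored_states):
    rec, _ = default_recording
    return rc.detect_ripples(rec.lfp_ca1, rec.fs_ca1, scored_states)


@pytest.fixture(scope="session")
def trough_times(detected_ripples):
    return np.array([e.trough_time for e in detected_ripples])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
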