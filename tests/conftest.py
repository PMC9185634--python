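import numpy as np
import pytest

from ripfatigue.signal_model import Annotation, Recording, TimeSeriesChannel
from ripfatigue.synthetic_data import StudyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_rip_config():
    """A short RIP-only study: cheap enough for per-test generation."""
    return StudyConfig(n_subjects=3, trial_length_s=90.0, rest_length_s=15.0,
                       inter_trial_gap_s=5.0, sampling_rate_hz=200.0,
                       modalities=("rip",))


@pytest.fixture
def tiny_recording(rng):
    """A hand-built 3-channel recording with one trial annotation."""
    rate = 100.0
    n = 3000
    t = np.arange(n) / rate
    channels = {
        "rip_chest": TimeSeriesChannel("rip_chest", np.sin(2 * np.pi * 0.25 * t), rate, "a.u."),
        "rip_abdomen": TimeSeriesChannel("rip_abdomen", np.cos(2 * np.pi * 0.25 * t), rate, "a.u."),
        "acc_y": TimeSeriesChannel("acc_y", rng.standard_normal(n), rate, "g"),
    }
    anns = [Annotation("rest", "rest_pre", 0.0, 5.0),
            Annotation("trial", "Baseline", 5.0, 25.0),
            Annotation("mvc", "biceps", 26.0, 29.0)]
    return Recording("SUBJ", channels, anns, metadata={"age": 30})
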