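import numpy as np
import pytest

import respfatigue as rf


@pytest.fixture(scope="session")
def regular_ecg():
    """30 s surrogate ECG with perfectly regular beats (60 bpm)."""
    return rf.generate_surrogate_ecg(
        rf.SurrogateEcgSpec(
            duration=30, heart_rate=60, beat_jitter=0, shape_irregularity=0, seed=5
        )
    )


@pytest.fixture(scope="session")
def stationary_emg():
    """30 s stationary surrogate sEMG (constant 120 Hz mean frequency)."""
    return rf.generate_surrogate_emg(
        rf.SurrogateEmgSpec(duration=30, mnf_start=120, mnf_end=120, seed=3)
    )


@pytest.fixture(scope="session")
def bench05():
    """One full synthetic bench realization at EMG level 0.05."""
    from respfatigue.pipeline import make_bench

    return make_bench(1, etas=(0.05,))
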