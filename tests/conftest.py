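import numpy as np
import pytest

import pupaecg as p

FS = 2604.0

# canonical trapezoid beat used throughout: 1 mV, 10/30/20 ms segments
STD_SHAPE = p.BeatShape(amplitude=1e-3, rise_time=0.010,
                        plateau_time=0.030, fall_time=0.020)


@pytest.fixture
def std_shape():
    return STD_SHAPE


@pytest.fixture
def clean_train():
    """Noise-free 2 Hz trapezoid train, 10 s at 2604 Hz."""
    cfg = p.SyntheticConfig(heart_rate=2.0, duration=10.0,
                            sampling_rate=FS, beat_shape=STD_SHAPE)
    return p.generate_trace(cfg)


@pytest.fixture
def clean_config():
    return p.SyntheticConfig(heart_rate=2.0, duration=10.0,
                             sampling_rate=FS, beat_shape=STD_SHAPE)
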