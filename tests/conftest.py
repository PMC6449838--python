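import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vsmcquant import StimulusProtocol
from vsmcquant import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def protocol():
    return StimulusProtocol(control_time=60.0, drug_time=120.0, mp_window=100.0)


@pytest.fixture
def pulse_trace():
    """Factory for single-pulse noiseless traces in F/F0 units."""

    def make(onset=100.0, peak=110.0, amplitude=3.0, half_max_duration=10.0,
             shape="triangle", duration=300.0, frame_interval=1.0, noise_sd=0.0,
             seed=0):
        gt = syn.TraceGroundTruth(
            roi_id=0,
            events=[syn.EventSpec(onset, peak, amplitude, half_max_duration)],
            noise_sd=noise_sd,
        )
        return syn.generate_trace(gt, duration, frame_interval, seed=seed, shape=shape)

    return make


@pytest.fixture
def grid_layout():
    """Disk layout for a 3x3 grid of radius-5 cells in a 75x75 image."""
    return [(12 + 24 * (i // 3), 12 + 24 * (i % 3), 5) for i in range(9)], (75, 75)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
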