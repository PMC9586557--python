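import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resisleep.core import Channel, ChannelMeta, Hypnogram, Recording

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_hypnogram():
    """One hour: 120 wake, 180 NREM, 36 REM, 24 wake epochs."""
    labels = np.array(
        ["WAKE"] * 120 + ["NREM"] * 180 + ["REM"] * 36 + ["WAKE"] * 24)
    return Hypnogram(labels=labels, epoch_s=10.0, zt_start_s=0.0)


def make_recording(duration_s=60.0, rates=(400.0,), roles=("EEG_FRONTAL",),
                   seed=0, scale=50.0):
    rng = np.random.default_rng(seed)
    channels = []
    for role, fs in zip(roles, rates):
        lp = 30.0 if fs <= 800 else 1000.0
        data = (rng.standard_normal(int(duration_s * fs)) * scale).astype(np.float32)
        channels.append(Channel(ChannelMeta(role, fs, lp), data))
    return Recording(channels=channels, zt_start_s=0.0)


@pytest.fixture
def two_channel_recording():
    return make_recording(duration_s=60.0, rates=(400.0, 2000.0),
                          roles=("EEG_FRONTAL", "LFP_IL"), seed=3)
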