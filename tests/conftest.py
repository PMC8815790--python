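import numpy as np
import pytest

from calunmix.datatypes import NeuronMasks, VideoStack
from calunmix.synthdata import SynthConfig, _disk_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_disk_masks():
    """Two partially overlapping radius-5 disks on a 40x40 grid."""
    m1 = _disk_mask((20.0, 14.0), 5.0, 40, 40)
    m2 = _disk_mask((20.0, 24.0), 5.0, 40, 40)
    return NeuronMasks(np.stack([m1, m2]))


@pytest.fixture
def small_video(rng):
    """A 60-frame 20x20 raw video: flat baseline 10 plus unit noise."""
    data = 10.0 + rng.normal(0, 1.0, (60, 20, 20))
    return VideoStack(np.clip(data, 0, None).astype(np.float32), 30.0, "raw")


def make_transient_trace(T, spikes, amplitude=1.0, decay_s=0.2, frame_rate=30.0):
    """Spike train convolved with an exponential-decay template."""
    t = np.arange(int(10 * decay_s * frame_rate)) / frame_rate
    template = amplitude * np.exp(-t / decay_s)
    train = np.zeros(T)
    train[np.asarray(spikes)] = 1.0
    return np.convolve(train, template)[:T]


@pytest.fixture
def trace_fixture_cfg():
    return SynthConfig(n_neurons=4, spike_rate=0.2, T=3000, seed=7)
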