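import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from spindletopo.io_core import Montage
from spindletopo.montage import standard_montage_58
from spindletopo.synthetic import SynthConfig, generate_participant


@pytest.fixture(scope="session")
def montage58():
    return standard_montage_58()


@pytest.fixture(scope="session")
def montage20(montage58):
    return Montage(montage58.channel_labels[:20], montage58.xy[:20])


def make_participant(seed=0, **kwargs):
    """Small synthetic participant; keyword args override SynthConfig."""
    kwargs.setdefault("n_participants", 1)
    kwargs.setdefault("wake_duration_s", 120.0)
    kwargs.setdefault("sleep_duration_s", 480.0)
    kwargs.setdefault("seed", seed)
    config = SynthConfig(**kwargs)
    bundle, truth = generate_participant(config, "sub-01",
                                         np.random.default_rng(seed))
    return config, bundle, truth


@pytest.fixture(scope="session")
def strong_participant(montage20):
    """One participant with strong, unjittered events on 20 channels."""
    return make_participant(
        seed=101, montage=montage20, sleep_duration_s=720.0,
        spindle_snr=5.0, so_snr=4.0, amp_jitter=0.0,
        spindle_topo_range=(1.0, 1.0), so_topo_range=(1.0, 1.0),
    )


@pytest.fixture(scope="session")
def tiny_montage(montage58):
    return Montage(montage58.channel_labels[:6], montage58.xy[:6])
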