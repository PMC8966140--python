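import numpy as np
import pytest

from selfmotion.measures import TargetTrack
from selfmotion.scene import ParametricHarir


@pytest.fixture(scope="session")
def harir16k():
    """Parametric HARIR model at 16 kHz, shared (IRs are cached)."""
    return ParametricHarir(fs=16000)


@pytest.fixture(scope="session")
def harir44k():
    return ParametricHarir(fs=44100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def frontal_target():
    """Constant frontal target over 120 s (lecture-like situation)."""
    return TargetTrack(np.array([0.0, 120.0]), np.array([0.0, 0.0]))


def conversation_target(seed: int, duration: float = 120.0,
                        turn_mean: float = 5.0) -> TargetTrack:
    """Three talkers at -30/0/+30 deg with exponential turn durations."""
    rng = np.random.default_rng(seed)
    times, azs = [0.0], [30.0]
    t, cur = 0.0, 30.0
    talkers = [-30.0, 0.0, 30.0]
    while t < duration:
        t += rng.exponential(turn_mean)
        cur = float(rng.choice([a for a in talkers if a != cur]))
        times.append(t)
        azs.append(cur)
    return TargetTrack(np.array(times), np.array(azs))
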