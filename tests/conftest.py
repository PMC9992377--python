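import numpy as np
import pytest

import groupplv as gp


def tone(freq: float, seconds: float, fs: float = 128.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(seconds * fs))) / fs
    return np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """A 4-channel 9-s broadband recording with valid ratings."""
    signals = rng.standard_normal((4, int(9 * 128)))
    return gp.Recording(
        participant=0, video=0, signals=signals, fs=128.0,
        ratings=np.array([5.0, 6.0, 4.0, 3.0]),
        montage=gp.Montage(("c0", "c1", "c2", "c3")),
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    """2 participants x 4 videos x 9 s, gamma-separable conditions."""
    cfg = gp.separable_gamma_config(
        n_participants=2, n_videos=4, duration=9.0, seed=5)
    return cfg, [gp.simulate_participant(cfg, p) for p in range(2)]
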