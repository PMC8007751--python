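import numpy as np
import pytest

from ztweeg.synthetic import SimConfig, generate


@pytest.fixture(scope="session")
def small_sim():
    """A compact two-subject recording: 8 channels, 16-s trials, 4 frames."""
    cfg = SimConfig(
        n_subjects=2,
        n_channels=8,
        trial_len_s=16.0,
        kappa=4.0,
        shift=4.0,
        trials_per_emotion=4,
        seed=123,
    )
    store, gt = generate(cfg)
    return cfg, store, gt


@pytest.fixture(scope="session")
def default_sim():
    """One subject at the study's default conditions (60-s trials, 32 channels,
    10 trials per emotion, effect 2.0, SNR 3)."""
    cfg = SimConfig(n_subjects=1, seed=11)
    store, gt = generate(cfg)
    return cfg, store, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
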