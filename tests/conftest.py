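import numpy as np
import pytest

import irplab as il


@pytest.fixture(scope="session")
def montage64():
    return il.make_montage(64)


@pytest.fixture(scope="session")
def small_session():
    """A 30+30-trial visual session at 250 Hz with its ground truth."""
    cfg = il.vice_config(seed=11, fs=250.0, n_go=30, n_nogo=30)
    rec, gt = il.simulate_session(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def small_epochs(small_session):
    """Preprocessed (no resampling needed) epochs of the small session."""
    _, rec, _ = small_session
    epochs, repochs = il.preprocess_session(rec, target_fs=None)
    return epochs, repochs


@pytest.fixture(scope="session")
def noiseless_session():
    """Noise- and jitter-free session: evoked components only."""
    cfg = il.vice_config(seed=12, fs=250.0, n_go=20, n_nogo=20,
                         background_level=0.0, latency_jitter_sd=0.0)
    rec, gt = il.simulate_session(cfg)
    return cfg, rec, gt


def sine_recording(freq, fs=250.0, duration=8.0, n_channels=8):
    """Recording whose channels all carry one pure sinusoid."""
    import pandas as pd

    t = np.arange(int(duration * fs)) / fs
    montage = il.make_montage(n_channels)
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    beh = pd.DataFrame(columns=["condition", "rt", "correct"])
    return il.Recording(data=data, fs=fs, montage=montage, events=(),
                        behavior=beh)
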