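import numpy as np
import pytest

from reachnet.preprocess import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_epochs(data, fs=512.0, tmin=-1.0, labels=None, targets=None):
    """Small EpochSet helper used across test modules."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    time = tmin + np.arange(n_samp) / fs
    if labels is None:
        labels = [f"ch{i}" for i in range(n_ch)]
    if targets is None:
        targets = np.ones(n_trials, dtype=int)
    return EpochSet(data=data, time=time, fs=fs, labels=labels, targets=targets)


@pytest.fixture
def sinusoid_epochs():
    """60 trials of a 10 Hz tone whose amplitude halves from t = 0.5 s on,
    on channel 0; channel 1 is stationary. Tiny noise keeps power positive."""
    rng = np.random.default_rng(7)
    fs, tmin, tmax = 512.0, -1.0, 3.0
    t = tmin + np.arange(int((tmax - tmin) * fs)) / fs
    gain = np.where(t < 0.5, 1.0, 0.5)
    trials = []
    for _ in range(60):
        ph = rng.uniform(0, 2 * np.pi, size=2)
        ch0 = gain * np.sin(2 * np.pi * 10 * t + ph[0])
        ch1 = np.sin(2 * np.pi * 10 * t + ph[1])
        trials.append(np.stack([ch0, ch1]) + 0.01 * rng.standard_normal((2, t.size)))
    return make_epochs(np.stack(trials), fs=fs, tmin=tmin)
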