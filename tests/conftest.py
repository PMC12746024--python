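import numpy as np
import pytest

from infantmmr.containers import DEVIANT, STANDARD, EpochSet
from infantmmr.montage import build_default_montage


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


def make_epochs(data, rate=1000.0, window=(-200.0, 799.0), labels=None,
                channel_names=None, mask=None):
    """EpochSet factory for tests."""
    data = np.asarray(data, float)
    n_trials, n_ch, _ = data.shape
    if labels is None:
        labels = [STANDARD] * n_trials
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_ch))
    return EpochSet(
        data=data, window_ms=window, sampling_rate=rate,
        trial_labels=np.asarray(labels, dtype=object),
        trial_onsets=np.arange(n_trials) * 1600,
        channel_names=tuple(channel_names), rejection_mask=mask,
    )


@pytest.fixture
def epochs_factory():
    return make_epochs
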