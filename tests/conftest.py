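import numpy as np
import pytest

from alphabold import synth
from alphabold.eeg import EEGRecording


@pytest.fixture
def small_config():
    """Down-scaled study conditions for fast unit tests: short recording,
    lower EEG rate, small voxel grid."""
    return synth.SimConfig(
        fs_eeg=500.0,
        duration=62.4,  # 24 volumes of 2.6 s
        n_volumes=24,
        grid_shape=(8, 8, 8),
        group_sizes={"AD": 3, "HC": 3},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(data, fs, labels=None, markers=None):
    n_ch = data.shape[0]
    if labels is None:
        base = ["O1", "O2", "Oz", "Pz", "Cz", "Fz", "ECG"]
        labels = base[:n_ch] if n_ch <= len(base) else (
            base[:-1] + [f"C{i}" for i in range(n_ch - len(base))] + ["ECG"])
    return EEGRecording(data=data, fs=fs, channel_labels=list(labels),
                        markers=markers or [])
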