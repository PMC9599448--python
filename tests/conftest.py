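import numpy as np
import pytest

from brainrate.montage import standard_montage_1020
from brainrate.synth import DEAP_CHANNELS


@pytest.fixture(scope="session")
def deap_channels():
    """The 32-channel layout of the emulated study (incl. the common P03 slip)."""
    return ("Fp1, AF3, F3, F7, FC5, FC1, C3, T7, CP5, CP1, P3, P7, P03, O1, Oz, "
            "Pz, Fp2, AF4, Fz, F4, F8, FC6, FC2, Cz, C4, T8, CP6, CP2, P4, P8, "
            "PO4, O2").split(", ")


@pytest.fixture(scope="session")
def montage32(deap_channels):
    return standard_montage_1020(deap_channels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recording_small():
    """A 4-channel, 8-s synthetic recording with mixed rhythms."""
    from brainrate.io import EEGRecording

    fs = 128.0
    t = np.arange(int(8 * fs)) / fs
    g = np.random.default_rng(7)
    data = np.stack([
        10 * np.sin(2 * np.pi * 10 * t) + g.normal(0, 1, t.size),
        5 * np.sin(2 * np.pi * 6 * t) + g.normal(0, 1, t.size),
        3 * np.sin(2 * np.pi * 21 * t) + g.normal(0, 1, t.size),
        g.normal(0, 2, t.size),
    ])
    return EEGRecording(data=data, fs=fs, channel_names=["O1", "Fz", "C3", "Cz"],
                        participant_id="p01", trial_id="t01")
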