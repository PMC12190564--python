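import numpy as np
import pytest

from qeegflow.preprocess import MONTAGE_1020, TIMEPOINTS, EpochArray, RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, rate_hz=200.0, montage=None, subject="S01", timepoint="baseline"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if montage is None:
        montage = tuple(f"ch{i}" for i in range(data.shape[0]))
    return RawRecording(subject=subject, timepoint=timepoint, montage=tuple(montage),
                        rate_hz=rate_hz, data=data)


def make_epochs(data, rate_hz=200.0, epoch_s=None, montage=None,
                subject="S01", timepoint="baseline"):
    """EpochArray from an epochs x channels x samples array."""
    data = np.asarray(data, dtype=float)
    if montage is None:
        montage = tuple(f"ch{i}" for i in range(data.shape[1]))
    if epoch_s is None:
        epoch_s = data.shape[2] / rate_hz
    return EpochArray(subject=subject, timepoint=timepoint, montage=tuple(montage),
                      rate_hz=rate_hz, epoch_s=epoch_s, data=data)


@pytest.fixture
def white_noise_epochs(rng):
    """60 five-second epochs of unit white noise on 2 channels at 200 Hz."""
    return make_epochs(rng.standard_normal((60, 2, 1000)), rate_hz=200.0)


@pytest.fixture
def feature_table(rng):
    """Complete synthetic feature table: 6 subjects x 19 channels x 8 time
    points for one metric/band, positive values."""
    import pandas as pd

    rows = []
    for s in range(6):
        for ch in MONTAGE_1020:
            base = 0.3 + 0.1 * rng.random()
            for tp in TIMEPOINTS:
                rows.append((f"S{s + 1:02d}", ch, tp, "rel_power", "theta",
                             base * (1 + 0.2 * rng.standard_normal())))
    return pd.DataFrame(rows, columns=["subject", "channel", "timepoint",
                                       "metric", "band", "value"])
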