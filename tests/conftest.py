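import numpy as np
import pytest

from gammase import EpochSet, FeatureMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, labels, fs=256.0, channel_names=None):
    return EpochSet(
        data=np.asarray(data, dtype=float),
        labels=np.asarray(labels, dtype=object),
        fs=fs,
        channel_names=channel_names or [],
        duration_s=np.asarray(data).shape[-1] / fs,
    )


def make_features(values, labels, band=(30.0, 55.0)):
    return FeatureMatrix(
        values=np.asarray(values, dtype=float),
        labels=np.asarray(labels, dtype=object),
        band=band,
    )


@pytest.fixture(scope="session")
def noise_epochs():
    """120 epochs x 8 channels of white noise, both groups exchangeable."""
    gen = np.random.default_rng(7)
    data = gen.standard_normal((120, 8, 256))
    labels = np.asarray(["alcoholic"] * 60 + ["control"] * 60, dtype=object)
    return make_epochs(data, labels)
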