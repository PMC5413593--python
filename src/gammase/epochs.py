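"""Core in-memory containers for multichannel ERP epochs and their features.

The analysis operates on 1-s windows ("epochs") of a multichannel EEG
recording, each labeled with the subject group (``alcoholic`` or
``control``), and on the per-epoch, per-channel spectral-entropy feature
matrix derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantError

#: The two recognized group labels. ``alcoholic`` is the positive class
#: throughout the evaluation code.
GROUP_LABELS = ("alcoholic", "control")
POSITIVE_LABEL = "alcoholic"


def _check_labels(labels: np.ndarray, n: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    if labels.ndim != 1 or labels.shape[0] != n:
        raise InvariantError(
            f"expected one label per epoch ({n}), got shape {labels.shape}"
        )
    bad = sorted({str(v) for v in labels} - set(GROUP_LABELS))
    if bad:
        raise InvariantError(f"unknown group label(s) {bad}; expected {GROUP_LABELS}")
    return labels


@dataclass
class EpochSet:
    """Labeled tensor of multichannel EEG epochs.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal amplitudes in microvolts.
    labels : ndarray of str, shape (n_epochs,)
        Group tag per epoch, each in ``{"alcoholic", "control"}``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel names, in acquisition order.
    duration_s : float
        Epoch length in seconds; ``round(fs * duration_s)`` must equal the
        sample dimension.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvariantError(
                f"data must be [epoch][channel][sample], got ndim={self.data.ndim}"
            )
        n_epochs, n_channels, n_samples = self.data.shape
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(n_channels)]
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise InvariantError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if len(set(self.channel_names)) != n_channels:
            raise InvariantError("channel names must be unique")
        expected = int(round(self.fs * self.duration_s))
        if n_samples != expected:
            raise InvariantError(
                f"samples per epoch ({n_samples}) != round(fs*duration) ({expected})"
            )
        self.labels = _check_labels(self.labels, n_epochs)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def group_mask(self, label: str) -> np.ndarray:
        return np.asarray([lab == label for lab in self.labels], dtype=bool)


@dataclass
class FeatureMatrix:
    """Per-epoch, per-channel normalized spectral entropy with group labels.

    ``values[e, c]`` is the SE of channel ``c`` in epoch ``e``; every value
    lies in [0, 1]. ``band`` records the (low, high) Hz range the entropy
    was computed over.
    """

    values: np.ndarray
    labels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    band: tuple[float, float] = (30.0, 55.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvariantError("feature values must be [epoch][channel]")
        n_epochs, n_channels = self.values.shape
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(n_channels)]
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise InvariantError("one name per feature column required")
        if len(set(self.channel_names)) != n_channels:
            raise InvariantError("channel names must be unique")
        if self.values.size and (
            np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12
        ):
            raise InvariantError("spectral entropy values must lie in [0, 1]")
        self.labels = _check_labels(self.labels, n_epochs)
        self.band = (float(self.band[0]), float(self.band[1]))

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def group_values(self, label: str) -> np.ndarray:
        mask = np.asarray([lab == label for lab in self.labels], dtype=bool)
        return self.values[mask]
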