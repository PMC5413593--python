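"""Normalized spectral entropy of gamma-band epochs.

The feature is the Shannon entropy of the in-band power spectrum treated
as a probability distribution, normalized by ``log N`` so that it lies in
[0, 1]::

    SE[f1, f2] = -(1 / log N[f1, f2]) * sum_i  P_n(f_i) log P_n(f_i)

where ``P_n(f_i) = P(f_i) / sum_band P`` and ``N[f1, f2]`` is the number
of spectral bins with ``f1 <= f_i <= f2`` (both edges included). A value
near 1 means the in-band power is spread evenly over the band (high
spectral disorder); a value near 0 means it is concentrated in a single
component. The normalization makes SE invariant to overall amplitude
scaling and to the logarithm base.

The spectral estimate is a single-window magnitude-squared FFT
periodogram of the full epoch, with no taper and no segment averaging:
a 1-s epoch at 256 Hz then gives exactly 1-Hz bins, so the 30–55 Hz band
contains N = 26 bins and the band edges are bin-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet, FeatureMatrix
from .errors import (
    BandTooNarrowError,
    DegenerateSpectrumError,
    GammaseError,
    LengthError,
)
from .preprocess import FilterSpec, extract_gamma

GAMMA_BAND = (30.0, 55.0)


@dataclass
class Spectrum:
    """One-sided power spectrum of a single trace (µV² per bin)."""

    freqs: np.ndarray
    power: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise GammaseError("freqs and power must have the same length")
        if np.any(np.diff(self.freqs) <= 0):
            raise GammaseError("freqs must be strictly increasing")
        if self.power.size and self.power.min() < 0:
            raise GammaseError("power must be nonnegative")


def power_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """One-sided periodogram with Parseval-consistent normalization.

    ``P[k] = |X[k]|^2 / n``, with non-DC, non-Nyquist bins doubled, so
    the one-sided powers sum to the signal energy ``sum(x^2)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise LengthError(f"need a 1-D trace of >= 2 samples, got shape {x.shape}")
    n = x.size
    X = np.fft.rfft(x)
    p = np.abs(X) ** 2 / n
    p[1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is not duplicated in the two-sided spectrum
        p[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(freqs=freqs, power=p, resolution_hz=fs / n)


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Boolean mask of bins with f1 <= f <= f2, inclusive at both edges."""
    f1, f2 = band
    tol = 1e-9
    return (freqs >= f1 - tol) & (freqs <= f2 + tol)


def spectral_entropy(sp: Spectrum, band: tuple[float, float] = GAMMA_BAND) -> float:
    """Normalized spectral entropy of the spectrum restricted to ``band``."""
    mask = band_mask(sp.freqs, band)
    n_bins = int(mask.sum())
    if n_bins < 2:
        raise BandTooNarrowError(
            f"band {band} contains {n_bins} spectral bin(s); need >= 2"
        )
    p = sp.power[mask]
    total = p.sum()
    if total <= 0:
        raise DegenerateSpectrumError(f"all in-band power in {band} is zero")
    pn = p / total
    nz = pn > 0
    h = -np.sum(pn[nz] * np.log(pn[nz]))  # 0*log(0) := 0 by continuity
    return float(np.clip(h / np.log(n_bins), 0.0, 1.0))


def _entropy_rows(power: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorized normalized entropy over the last axis of a power array."""
    totals = power.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise DegenerateSpectrumError("all in-band power is zero for some trace")
    pn = power / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pn > 0, pn * np.log(pn), 0.0)
    return np.clip(-terms.sum(axis=-1) / np.log(n_bins), 0.0, 1.0)


def build_feature_matrix(
    es: EpochSet, band: tuple[float, float] = GAMMA_BAND
) -> FeatureMatrix:
    """Spectral entropy of every (epoch, channel) trace of ``es``.

    Rows are epochs and columns are channels — the transpose of the
    channels-by-epochs orientation sometimes used to quote the feature-set
    dimension — so the matrix is in the conventional sample-by-feature
    layout. Labels are carried through unchanged.
    """
    if es.n_epochs == 0:
        raise LengthError("cannot build features from an empty EpochSet")
    n = es.n_samples
    X = np.fft.rfft(es.data, axis=-1)
    power = np.abs(X) ** 2 / n
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / es.fs)
    mask = band_mask(freqs, band)
    n_bins = int(mask.sum())
    if n_bins < 2:
        raise BandTooNarrowError(
            f"band {band} contains {n_bins} spectral bin(s); need >= 2"
        )
    inband = power[..., mask]
    totals = inband.sum(axis=-1)
    if np.any(totals <= 0):
        e, c = np.argwhere(totals <= 0)[0]
        raise DegenerateSpectrumError(
            f"all in-band power is zero at (epoch {e}, channel {c})"
        )
    values = _entropy_rows(inband, n_bins)
    return FeatureMatrix(
        values=values,
        labels=es.labels.copy(),
        channel_names=list(es.channel_names),
        band=band,
    )


def gamma_se_features(
    es: EpochSet,
    spec: FilterSpec | None = None,
    band: tuple[float, float] = GAMMA_BAND,
    filtered: bool = True,
) -> FeatureMatrix:
    """Full feature pathway: gamma filtering then in-band spectral entropy.

    ``filtered=False`` skips the band-pass and computes the entropy on the
    raw signal's band bins — useful for sensitivity analysis of the filter
    stage, since the band restriction already discards out-of-band bins.
    """
    if filtered:
        es = extract_gamma(es, spec)
    return build_feature_matrix(es, band)
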