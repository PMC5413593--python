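"""Synthetic two-group multichannel ERP epochs with planted gamma-band
complexity differences.

The generator emulates the statistical structure the analysis assumes:
1-s multichannel epochs from two groups (alcoholic / control) in which a
designated subset of channels carries a group difference in gamma-band
spectral *complexity*, while all remaining channels are exchangeable
between groups.

Each channel trace is a mixture inside the gamma band plus an
out-of-band background::

    x = sqrt(w)     * (band-limited Gaussian noise, 30-55 Hz)
      + sqrt(1 - w) * (pure tone at 40 Hz, random phase)
      + 1/f background below 30 Hz

The mixing weight ``w`` is the complexity dial — the fraction of in-band
power carried by the broadband noise component (both components have
unit power, so power mixes linearly in ``w``): ``w = 0`` concentrates
all in-band power in one bin (spectral entropy near 0) and ``w = 1``
spreads it over the whole band (entropy near 1). Linear power mixing
keeps the dial's slope away from zero over the whole range, so mean
entropy is strictly increasing in ``w`` at practical sample sizes. Complexity — not
amplitude — is manipulated because normalized spectral entropy is
invariant to power scaling, so an amplitude manipulation would be
invisible to the feature. The 1/f background gives the band-pass filter
real out-of-band energy to remove.

Non-planted channels use the same ``w`` for both groups. Planted
channels use a larger ``w`` for the alcoholic group (more disorder,
higher entropy). The ``effect`` knob is expressed directly in feature
units (target mean SE difference); an internal pilot simulation maps it
to the required weight increment by measuring mean SE over a weight grid
through the exact filtering + entropy pathway the main pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .epochs import EpochSet
from .errors import CalibrationError, InvariantError
from .features import GAMMA_BAND, build_feature_matrix
from .preprocess import FilterSpec, design_bandpass, zero_phase_filter

TONE_HZ = 40.0
#: Out-of-band (1/f) background power relative to unit in-band component power.
BACKGROUND_POWER = 1.0
#: Overall amplitude scale, microvolts RMS of the in-band components.
AMPLITUDE_UV = 10.0
#: Epochs per grid point in the calibration pilot.
_PILOT_EPOCHS = 100
_PILOT_SEED = 202_309


@dataclass(frozen=True)
class SynthConfig:
    """Study-shape parameters for the synthetic generator.

    ``effect`` is the target alcoholic-minus-control mean SE difference in
    the planted channels, in entropy units (dimensionless, [0, 0.5]);
    ``base_complexity`` is the tone/noise mixing weight shared by all
    non-planted channels and by the control group everywhere.
    """

    n_per_group: int
    n_channels: int = 61
    fs: float = 256.0
    duration_s: float = 1.0
    planted_channels: tuple[int, ...] = ()
    effect: float = 0.0
    base_complexity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_channels", tuple(sorted(set(int(c) for c in self.planted_channels)))
        )
        if self.n_per_group < 2:
            raise InvariantError("n_per_group must be >= 2")
        if any(not 0 <= c < self.n_channels for c in self.planted_channels):
            raise InvariantError(
                f"planted channels {self.planted_channels} outside "
                f"0..{self.n_channels - 1}"
            )
        if self.effect < 0:
            raise InvariantError("effect must be >= 0")
        if not 0 <= self.base_complexity <= 1:
            raise InvariantError("base_complexity must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def save_config(cfg: SynthConfig, path) -> None:
    """Serialize a config as a flat ``key = value`` text file."""
    with open(path, "w") as fh:
        for key, val in vars(cfg).items():
            if key == "planted_channels":
                val = ",".join(str(c) for c in val)
            fh.write(f"{key} = {val}\n")


def load_config(path) -> SynthConfig:
    """Read a config written by :func:`save_config`."""
    kwargs: dict = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "planted_channels":
                kwargs[key] = tuple(int(c) for c in val.split(",") if c)
            elif key in ("n_per_group", "n_channels", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
    return SynthConfig(**kwargs)


# ---------------------------------------------------------------------------
# Signal construction
# ---------------------------------------------------------------------------

def _component_bank(
    rng: np.random.Generator, n_epochs: int, n_channels: int, n: int, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-power noise, tone and background components per (epoch, channel)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = (n_epochs, n_channels)

    inband = (freqs >= GAMMA_BAND[0] - 1e-9) & (freqs <= GAMMA_BAND[1] + 1e-9)
    nb = int(inband.sum())
    spec = np.zeros((*shape, freqs.size), dtype=complex)
    spec[..., inband] = rng.standard_normal((*shape, nb)) + 1j * rng.standard_normal(
        (*shape, nb)
    )
    noise = np.fft.irfft(spec, n)
    noise /= np.sqrt(np.mean(noise**2, axis=-1, keepdims=True))

    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(*shape, 1))
    tone = np.sqrt(2.0) * np.cos(2.0 * np.pi * TONE_HZ * t + phase)

    low = (freqs > 0) & (freqs < GAMMA_BAND[0])
    nl = int(low.sum())
    bg_spec = np.zeros((*shape, freqs.size), dtype=complex)
    amp = 1.0 / freqs[low]
    bg_spec[..., low] = amp * (
        rng.standard_normal((*shape, nl)) + 1j * rng.standard_normal((*shape, nl))
    )
    background = np.fft.irfft(bg_spec, n)
    background /= np.sqrt(np.mean(background**2, axis=-1, keepdims=True))
    background *= np.sqrt(BACKGROUND_POWER)
    return noise, tone, background


def _synth_group(
    rng: np.random.Generator,
    n_epochs: int,
    weights: np.ndarray,
    n: int,
    fs: float,
) -> np.ndarray:
    """Epochs for one group; ``weights[c]`` is channel c's mixing weight."""
    n_channels = weights.size
    noise, tone, background = _component_bank(rng, n_epochs, n_channels, n, fs)
    w = weights[np.newaxis, :, np.newaxis]
    return AMPLITUDE_UV * (
        np.sqrt(w) * noise + np.sqrt(1.0 - w) * tone + background
    )


# ---------------------------------------------------------------------------
# Effect-size calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _mean_se_curve(fs: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pilot estimate of mean SE as a function of the mixing weight w.

    Runs the exact feature pathway of the main pipeline (gamma band-pass,
    then in-band normalized spectral entropy) on single-channel pilot
    epochs for a fixed weight grid; uses a fixed internal seed so the
    calibration is a pure function of the sampling geometry.
    """
    rng = np.random.default_rng(_PILOT_SEED)
    grid = np.linspace(0.0, 1.0, 21)
    sos = design_bandpass(FilterSpec(fs=fs))
    means = np.empty_like(grid)
    for i, w in enumerate(grid):
        x = _synth_group(rng, _PILOT_EPOCHS, np.asarray([w]), n, fs)
        filtered = zero_phase_filter(x, sos)
        es = EpochSet(
            data=filtered,
            labels=np.asarray(["control"] * _PILOT_EPOCHS, dtype=object),
            fs=fs,
            duration_s=n / fs,
        )
        means[i] = build_feature_matrix(es).values.mean()
    # enforce monotonicity for stable inversion (pilot noise is ~1e-2)
    means = np.maximum.accumulate(means)
    return grid, means


def calibrate_weight(cfg: SynthConfig) -> float:
    """Alcoholic-group weight for planted channels realizing ``cfg.effect``.

    Inverts the pilot mean-SE(w) curve at base SE + effect. Raises
    :class:`CalibrationError` when the target exceeds what w = 1 delivers.
    """
    if cfg.effect == 0:
        return cfg.base_complexity
    grid, means = _mean_se_curve(cfg.fs, cfg.n_samples)
    base_se = float(np.interp(cfg.base_complexity, grid, means))
    target = base_se + cfg.effect
    if target > means[-1]:
        raise CalibrationError(
            f"effect {cfg.effect} needs mean SE {target:.3f} but the maximum "
            f"attainable (w=1) is {means[-1]:.3f}"
        )
    return float(np.interp(target, means, grid))


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def generate_epochs(cfg: SynthConfig) -> EpochSet:
    """Generate ``2 * cfg.n_per_group`` labeled epochs.

    Alcoholic epochs come first, then controls. Identical configs (seed
    included) produce bit-identical tensors.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    w_control = np.full(cfg.n_channels, cfg.base_complexity)
    w_alcoholic = w_control.copy()
    if cfg.planted_channels and cfg.effect > 0:
        w_alcoholic[list(cfg.planted_channels)] = calibrate_weight(cfg)

    alco = _synth_group(rng, cfg.n_per_group, w_alcoholic, n, cfg.fs)
    ctrl = _synth_group(rng, cfg.n_per_group, w_control, n, cfg.fs)
    data = np.concatenate([alco, ctrl], axis=0)
    labels = np.asarray(
        ["alcoholic"] * cfg.n_per_group + ["control"] * cfg.n_per_group, dtype=object
    )
    return EpochSet(data=data, labels=labels, fs=cfg.fs, duration_s=cfg.duration_s)
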