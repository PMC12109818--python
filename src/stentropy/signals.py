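"""Synthetic test signals and multichannel emotion-EEG emulation.

Two families of inputs are generated here:

* deterministic single-channel test signals (pure sines, linear
  swept-frequency chirps, amplitude ramps) used to study how frequency
  and amplitude drive the Stockwell entropy, and

* randomized multichannel three-class "emotive EEG" datasets: a 1/f^alpha
  Gaussian background on every channel plus band-limited noise whose
  variance is boosted on class-specific channel subsets.  This emulates
  the structure of 62-channel, 200 Hz emotion recordings (3-s epochs,
  labels 1/0/-1) closely enough to exercise the full
  transform -> entropy -> CSP -> classifier pipeline without any
  external download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stockwell import SignalEpoch

__all__ = ["SignalSpec", "EmotiveEEGSpec", "make_signal", "make_emotive_dataset"]

_KINDS = ("sine", "chirp", "amp_ramp_sine", "fixed_freq_amp_ramp")


@dataclass
class SignalSpec:
    """Recipe for one deterministic test signal.

    kind
        ``sine``: constant frequency ``f0``, constant amplitude
        ``amplitude0``.
        ``chirp``: linear frequency sweep ``f0 -> f1``, constant
        amplitude.
        ``amp_ramp_sine``: linear sweep ``f0 -> f1`` with a linear
        amplitude ramp ``amplitude0 -> amplitude1``.
        ``fixed_freq_amp_ramp``: constant frequency ``f0`` with a linear
        amplitude ramp.
    """

    kind: str = "sine"
    f0: float = 5.0
    f1: float | None = None
    amplitude0: float = 1.0
    amplitude1: float | None = None
    duration: float = 3.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.f1 is None:
            self.f1 = self.f0
        if self.amplitude1 is None:
            self.amplitude1 = self.amplitude0
        nyquist = self.fs / 2.0
        for name, f in (("f0", self.f0), ("f1", self.f1)):
            if not 0 <= f < nyquist:
                raise ValueError(f"{name}={f} must lie in [0, fs/2)")
        for name, a in (("amplitude0", self.amplitude0), ("amplitude1", self.amplitude1)):
            if a < 0:
                raise ValueError(f"{name}={a} must be non-negative")
        if self.kind in ("sine", "fixed_freq_amp_ramp") and self.f1 != self.f0:
            raise ValueError(f"f1 must equal f0 for kind {self.kind!r}")
        if self.kind in ("sine", "chirp") and self.amplitude1 != self.amplitude0:
            raise ValueError(
                f"amplitude1 must equal amplitude0 for kind {self.kind!r}"
            )


def make_signal(spec: SignalSpec) -> SignalEpoch:
    """Render a :class:`SignalSpec` into a single-channel epoch.

    The chirp phase is ``phi(t) = 2 pi (f0 t + (f1 - f0) t^2 / (2 D))``
    (linear instantaneous frequency ``f0 -> f1`` over the duration
    ``D``); amplitude ramps interpolate sample-wise linearly.
    """
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    sweep = (spec.f1 - spec.f0) / (2.0 * spec.duration)
    phase = 2.0 * np.pi * (spec.f0 * t + sweep * t**2)
    envelope = spec.amplitude0 + (spec.amplitude1 - spec.amplitude0) * t / spec.duration
    return SignalEpoch(data=envelope * np.sin(phase), fs=spec.fs, label=None)


@dataclass
class EmotiveEEGSpec:
    """Recipe for a randomized three-class multichannel dataset.

    Every epoch is an independent 1/f^alpha Gaussian background (unit
    variance per channel) plus band-limited Gaussian noise inside
    ``class_band`` on all channels (standard deviation
    ``band_noise_std``); on the epoch's class-specific
    ``effect_channels`` the band-noise *variance* is multiplied by
    ``effect_gain``.  With ``effect_gain=1`` the three classes are
    statistically identical (a null construction).
    """

    n_channels: int = 62
    n_epochs_per_class: int = 60
    fs: float = 200.0
    epoch_len: float = 3.0
    class_band: tuple[float, float] = (30.0, 46.0)
    effect_channels: dict[int, tuple[int, ...]] = field(default_factory=dict)
    effect_gain: float = 6.0
    band_noise_std: float = 1.5
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_epochs_per_class < 1:
            raise ValueError("n_channels and n_epochs_per_class must be >= 1")
        if self.effect_gain < 1:
            raise ValueError(f"effect_gain={self.effect_gain} must be >= 1")
        lo, hi = self.class_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError(f"class_band {self.class_band} must lie in (0, fs/2)")
        if not self.effect_channels:
            # Disjoint 8-channel subsets per class (clipped for small montages).
            w = max(1, min(8, self.n_channels // 3))
            self.effect_channels = {
                1: tuple(range(0, w)),
                0: tuple(range(w, 2 * w)),
                -1: tuple(range(2 * w, 3 * w)),
            }
        for lab, chans in self.effect_channels.items():
            if lab not in (1, 0, -1):
                raise ValueError(f"effect_channels key {lab} is not a valid label")
            if any(c < 0 or c >= self.n_channels for c in chans):
                raise ValueError(
                    f"effect_channels[{lab}] out of range [0, {self.n_channels})"
                )
        subsets = [frozenset(v) for v in self.effect_channels.values()]
        if len(subsets) > 1 and len(set(subsets)) == 1:
            warnings.warn(
                "identical effect channel subsets for all classes: classes are "
                "inseparable by construction",
                stacklevel=2,
            )


def _colored_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, alpha: float
) -> np.ndarray:
    """1/f^alpha Gaussian noise, unit sample variance per channel."""
    spec = np.fft.rfft(rng.standard_normal((n_channels, n)), axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _band_noise(
    rng: np.random.Generator,
    n_channels: int,
    n: int,
    fs: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Brick-wall band-limited Gaussian noise, unit variance per channel."""
    spec = np.fft.rfft(rng.standard_normal((n_channels, n)), axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[:, (f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def make_emotive_dataset(spec: EmotiveEEGSpec) -> list[SignalEpoch]:
    """Generate labeled epochs, ``n_epochs_per_class`` per label in {1, 0, -1}.

    Output is deterministic for a fixed spec (including ``seed``):
    identical parameters produce bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.epoch_len * spec.fs))
    lo, hi = spec.class_band
    epochs: list[SignalEpoch] = []
    for label in (1, 0, -1):
        eff = np.asarray(spec.effect_channels.get(label, ()), dtype=int)
        std = np.full(spec.n_channels, spec.band_noise_std)
        std[eff] = spec.band_noise_std * np.sqrt(spec.effect_gain)
        for _ in range(spec.n_epochs_per_class):
            data = _colored_noise(rng, spec.n_channels, n, spec.fs, spec.noise_exponent)
            data += std[:, None] * _band_noise(rng, spec.n_channels, n, spec.fs, lo, hi)
            epochs.append(SignalEpoch(data=data, fs=spec.fs, label=label))
    return epochs
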