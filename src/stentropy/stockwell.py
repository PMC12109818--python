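"""Discrete Stockwell (S-)transform and frequency-band grouping.

The S-transform decomposes a signal into complex time-frequency
coefficients ``S(tau, f)`` using a Gaussian analysis window whose
temporal width shrinks as ``1/f``: fine time resolution at high
frequency, fine frequency resolution at low frequency.  This module
implements the classical FFT formulation: for each analysis frequency
``f`` the signal spectrum is shifted by ``f``, multiplied by a real
Gaussian voice window ``exp(-2 pi^2 nu^2 width^2 / f^2)`` and
inverse-transformed.  With this normalisation the defining marginal
identity holds exactly: summing ``S(tau, f)`` over all ``tau`` recovers
the discrete Fourier spectrum ``X(f)`` at each analysis frequency.

Analysis frequencies live on the natural DFT grid of the epoch (bins at
multiples of ``1/duration``), clipped to ``[fmin, fmax]``; the zero
frequency is excluded.  No zero padding is applied, so the transform is
circular in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "SignalEpoch",
    "TimeFrequencyMap",
    "Band",
    "BandSeries",
    "DEFAULT_BANDS",
    "stransform",
    "band_group",
    "band_reconstruct",
]


@dataclass
class SignalEpoch:
    """One fixed-length multichannel window of raw signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Real-valued signal.  A 1-D array is promoted to one channel.
    fs : float
        Sampling rate in Hz.
    label : int or None
        Emotion-state code: 1 (positive), 0 (neutral), -1 (negative),
        or None for unlabeled data.
    t0 : float
        Epoch start time in seconds (provenance only).
    """

    data: np.ndarray
    fs: float
    label: int | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.label is not None and self.label not in (1, 0, -1):
            raise ValueError(f"label must be 1, 0, -1 or None, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


class Band(NamedTuple):
    """A named frequency interval in Hz."""

    name: str
    fmin: float
    fmax: float


#: The six analysis bands: full band plus the five canonical EEG rhythms,
#: with the Gamma band capped at 46 Hz.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("full", 0.1, 46.0),
    Band("delta", 0.1, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
    Band("gamma", 30.0, 46.0),
)


@dataclass
class TimeFrequencyMap:
    """Complex S-transform coefficients over channel x frequency x time."""

    coef: np.ndarray  # (n_channels, n_freqs, n_samples) complex
    freqs: np.ndarray  # (n_freqs,) Hz, strictly increasing
    fs: float
    width: float = 1.0

    @property
    def n_channels(self) -> int:
        return self.coef.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coef.shape[2]


@dataclass
class BandSeries:
    """Band-aggregated coefficient magnitudes, channel x band x time."""

    values: np.ndarray  # (n_channels, n_bands, n_samples) >= 0
    bands: tuple[Band, ...]
    fs: float = field(default=0.0)

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]


def _validate_transform_args(
    epoch: SignalEpoch, fmin: float, fmax: float, width: float
) -> None:
    nyquist = epoch.fs / 2.0
    if not 0 < fmin < fmax:
        raise ValueError(f"need 0 < fmin < fmax, got fmin={fmin}, fmax={fmax}")
    if fmax >= nyquist:
        raise ValueError(
            f"fmax={fmax} must be below the Nyquist frequency {nyquist} Hz"
        )
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if epoch.n_samples < 2:
        raise ValueError("epoch must contain at least 2 samples")


def stransform(
    epoch: SignalEpoch,
    fmin: float = 0.1,
    fmax: float = 46.0,
    width: float = 1.0,
) -> TimeFrequencyMap:
    """Discrete S-transform of every channel of an epoch.

    Parameters
    ----------
    epoch : SignalEpoch
        Input signal; all samples must be finite.
    fmin, fmax : float
        Analysis frequency range in Hz.  Frequencies are the DFT bins of
        the epoch (multiples of ``1/duration``) falling inside
        ``[fmin, fmax]``; ``fmax`` must be below Nyquist.
    width : float
        Gaussian window width factor.  The frequency-domain voice window
        has standard deviation ``f / (2 pi width)``, i.e. the temporal
        window narrows proportionally to ``1/f``; ``width = 1`` is the
        classical transform.

    Returns
    -------
    TimeFrequencyMap
        Complex coefficients, shape ``(n_channels, n_freqs, n_samples)``.

    Notes
    -----
    The transform is linear and satisfies the time-marginal identity
    ``sum_tau S(tau, f) == X(f)`` exactly (up to floating point), where
    ``X`` is the DFT of the input.
    """
    _validate_transform_args(epoch, fmin, fmax, width)
    x = epoch.data
    n = epoch.n_samples
    duration = n / epoch.fs

    m_all = np.arange(1, n // 2 + 1)
    f_all = m_all / duration
    sel = (f_all >= fmin) & (f_all <= fmax)
    ms = m_all[sel]
    freqs = f_all[sel]
    if ms.size == 0:
        raise ValueError(f"no analysis frequencies inside [{fmin}, {fmax}] Hz")

    X = np.fft.fft(x, axis=-1)
    nu = np.fft.fftfreq(n, d=1.0 / epoch.fs)
    # Voice windows: real Gaussians in the frequency domain, unit at nu=0
    # so each voice's time window integrates to one (amplitude preserving).
    gauss = np.exp(
        -2.0 * np.pi**2 * nu[None, :] ** 2 * width**2 / freqs[:, None] ** 2
    )
    idx = (np.arange(n)[None, :] + ms[:, None]) % n
    coef = np.fft.ifft(X[:, idx] * gauss[None, :, :], axis=-1)
    return TimeFrequencyMap(coef=coef, freqs=freqs, fs=epoch.fs, width=width)


def _band_mask(
    freqs: np.ndarray, band: Band, *, closed_right: bool
) -> np.ndarray:
    if closed_right:
        return (freqs >= band.fmin) & (freqs <= band.fmax)
    return (freqs >= band.fmin) & (freqs < band.fmax)


def band_group(
    tfr: TimeFrequencyMap, bands: Sequence[Band] = DEFAULT_BANDS
) -> BandSeries:
    """Group S-transform magnitudes into frequency bands.

    For each band and time point the aggregate is the mean of ``|coef|``
    over frequency bins with ``fmin <= f < fmax``; the final band in the
    sequence includes its upper edge so the top analysis frequency is
    not lost.  The half-open convention prevents double counting at the
    shared edges (4, 8, 12, 30 Hz).

    Raises
    ------
    ValueError
        If a band contains no analysis frequency bin (the error names
        the offending band).
    """
    bands = tuple(bands)
    mag = np.abs(tfr.coef)
    rows = []
    for i, band in enumerate(bands):
        mask = _band_mask(tfr.freqs, band, closed_right=(i == len(bands) - 1))
        if not mask.any():
            raise ValueError(
                f"band {band.name!r} [{band.fmin}, {band.fmax}) Hz contains "
                "no analysis frequency bins"
            )
        rows.append(mag[:, mask, :].mean(axis=1))
    return BandSeries(values=np.stack(rows, axis=1), bands=bands, fs=tfr.fs)


def band_reconstruct(
    tfr: TimeFrequencyMap, fmin: float, fmax: float
) -> np.ndarray:
    """Band-limited waveform via voice summation.

    Remodulates each voice by ``exp(2j pi f tau)`` and sums the real
    parts over all analysis frequencies inside the closed interval
    ``[fmin, fmax]``, yielding a real band-filtered version of the input
    (one row per channel).  For a pure tone on the frequency grid inside
    the band this reproduces the tone exactly up to a constant amplitude
    factor, independent of the window parameters.
    """
    mask = (tfr.freqs >= fmin) & (tfr.freqs <= fmax)
    if not mask.any():
        raise ValueError(f"no analysis frequency bins inside [{fmin}, {fmax}] Hz")
    t = np.arange(tfr.n_samples) / tfr.fs
    osc = np.exp(2j * np.pi * tfr.freqs[mask][:, None] * t[None, :])
    return np.real((tfr.coef[:, mask, :] * osc[None, :, :]).sum(axis=1))
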