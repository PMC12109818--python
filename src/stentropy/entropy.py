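"""Sliding-window differential entropy -- the "Stockwell entropy" feature.

Each window of ``k`` consecutive values of a band series is modelled as
draws from a Gaussian, whose differential entropy has the closed form

    h = 1/2 * ln(2 pi e sigma^2)   [nats]

so the feature reduces to the log of the local standard deviation.
Sliding the window one sample at a time over a series of length ``N``
yields an entropy sequence of length ``N - k + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .stockwell import BandSeries

__all__ = ["EntropySeries", "sliding_de", "stockwell_entropy", "VARIANCE_FLOOR"]

#: Variance floor applied before the logarithm.  Constant windows occur
#: for pure tones (constant S-transform magnitude); flooring keeps the
#: entropy finite instead of -inf.
VARIANCE_FLOOR = 1e-12


@dataclass
class EntropySeries:
    """Sliding-window differential entropy, channel x band x position."""

    values: np.ndarray  # (n_channels, n_bands, N - k + 1)
    window: int  # k, samples
    source_len: int  # N, samples

    def __post_init__(self) -> None:
        expected = self.source_len - self.window + 1
        if self.values.shape[-1] != expected:
            raise ValueError(
                f"entropy length {self.values.shape[-1]} != N - k + 1 = {expected}"
            )


def sliding_de(
    series: np.ndarray,
    k: int,
    *,
    estimator: str = "population",
    floor: float = VARIANCE_FLOOR,
) -> np.ndarray:
    """Sliding-window Gaussian differential entropy of a series.

    Parameters
    ----------
    series : ndarray
        Input values; the window slides along the last axis (length N).
    k : int
        Window width in samples, ``2 <= k <= N``; stride is 1.
    estimator : {"population", "sample"}
        Variance estimator: divide by ``k`` (the plug-in maximum
        likelihood estimate matching the Gaussian model; default) or by
        ``k - 1``.
    floor : float
        Lower bound applied to the variance before taking the log.

    Returns
    -------
    ndarray
        ``0.5 * ln(2 pi e var_i)`` for each window position, shape
        ``series.shape[:-1] + (N - k + 1,)``, in nats.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if k > n:
        raise ValueError(f"window k={k} exceeds series length N={n}")
    if k < 2:
        raise ValueError(f"window k={k} too small; variance needs k >= 2")
    if estimator not in ("population", "sample"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ddof = 0 if estimator == "population" else 1
    var = sliding_window_view(series, k, axis=-1).var(axis=-1, ddof=ddof)
    return 0.5 * np.log(2.0 * np.pi * np.e * np.maximum(var, floor))


def stockwell_entropy(
    bs: BandSeries,
    k: int,
    *,
    estimator: str = "population",
    floor: float = VARIANCE_FLOOR,
) -> EntropySeries:
    """Apply :func:`sliding_de` to every (channel, band) row of a band series.

    Rows are processed band by band to bound the memory of the sliding
    window view.  Errors from :func:`sliding_de` are re-raised with the
    offending band attached.
    """
    values = bs.values
    n = values.shape[-1]
    if k > n:
        raise ValueError(f"window k={k} exceeds series length N={n}")
    out = np.empty(values.shape[:-1] + (n - k + 1,), dtype=float)
    for b in range(values.shape[1]):
        try:
            out[:, b, :] = sliding_de(
                values[:, b, :], k, estimator=estimator, floor=floor
            )
        except ValueError as err:
            band = bs.bands[b].name if b < len(bs.bands) else str(b)
            raise ValueError(f"band {band!r}: {err}") from err
    return EntropySeries(values=out, window=k, source_len=n)
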