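"""Fourier-based comparison methods: pair-distance histogram and
autocorrelation of the smoothed boolean sequence.

Both are the standard ways to look for periods in sparse site data and
both are known to fail on complex motifs and on superposed periodic
trains; they are included so the solenoidal spectra can be compared
against them on identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solenoid import SiteSequence

__all__ = [
    "HistogramSpectrum",
    "AutocorrelationCurve",
    "pair_distance_histogram",
    "dft_of_histogram",
    "smooth_boolean",
    "autocorrelation",
    "dft_of_autocorrelation",
    "dominant_period",
]


@dataclass(frozen=True)
class HistogramSpectrum:
    """Binned pair-distance counts, optionally with their Fourier spectrum."""

    bin_width: int
    counts: np.ndarray = field(repr=False)
    periods: np.ndarray | None = field(default=None, repr=False)
    magnitudes: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class AutocorrelationCurve:
    lags: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    window: int = 0
    kernel: str = "square"


def pair_distance_histogram(sites: SiteSequence, bin_width: int = 50) -> HistogramSpectrum:
    """Histogram of |p_a - p_b| over all unordered site pairs."""
    if bin_width < 1:
        raise ValueError(f"bin width must be >= 1, got {bin_width}")
    if sites.n < 2:
        raise ValueError("need at least 2 sites")
    pos = sites.positions
    d = np.abs(pos[:, None] - pos[None, :])[np.triu_indices(sites.n, k=1)]
    counts = np.bincount(d // bin_width)
    return HistogramSpectrum(bin_width=bin_width, counts=counts)


def _dft_periods(values: np.ndarray, sample_spacing: float, pad_factor: int = 4):
    """Magnitude spectrum of a mean-subtracted series on a period axis.

    Zero-pads to ``pad_factor`` times the series length for peak
    readability; the k-th magnitude is reported at period
    ``sample_spacing * n_padded / k`` (the zero-frequency bin is dropped).
    """
    y = np.asarray(values, dtype=float)
    y = y - y.mean()
    n = int(pad_factor) * y.size
    mag = np.abs(np.fft.rfft(y, n))
    k = np.arange(1, mag.size)
    return sample_spacing * n / k, mag[1:]


def dft_of_histogram(hist: HistogramSpectrum, pad_factor: int = 4) -> HistogramSpectrum:
    """Attach the Fourier magnitude spectrum of the binned counts."""
    periods, mag = _dft_periods(hist.counts, hist.bin_width, pad_factor)
    return HistogramSpectrum(
        bin_width=hist.bin_width, counts=hist.counts, periods=periods, magnitudes=mag
    )


def dominant_period(
    periods: np.ndarray,
    magnitudes: np.ndarray,
    p_min: float | None = None,
    p_max: float | None = None,
) -> float:
    """Period of the largest Fourier magnitude within an optional band."""
    mask = np.ones(periods.size, dtype=bool)
    if p_min is not None:
        mask &= periods >= p_min
    if p_max is not None:
        mask &= periods <= p_max
    if not mask.any():
        raise ValueError("no Fourier component inside the requested band")
    idx = np.flatnonzero(mask)
    return float(periods[idx[np.argmax(magnitudes[idx])]])


def smooth_boolean(
    sites: SiteSequence, window: int = 1000, kernel: str = "square"
) -> np.ndarray:
    """Smooth the boolean indicator so products in the autocorrelation
    are not almost surely zero.

    Square kernel: position ``l`` becomes 1 if any site lies within
    ``window/2`` of it.  Gaussian kernel: superposition of unit-height
    Gaussians of standard deviation ``window/2`` (continuous values).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    length = sites.length
    if kernel == "square":
        half = window // 2
        delta = np.zeros(length + 1)
        lo = np.clip(sites.positions - half, 0, length)
        hi = np.clip(sites.positions + half + 1, 0, length)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        return (np.cumsum(delta[:-1]) > 0).astype(float)
    if kernel == "gaussian":
        sigma = window / 2.0
        grid = np.arange(length, dtype=float)
        out = np.zeros(length)
        for p in sites.positions:
            lo, hi = max(0, int(p - 5 * sigma)), min(length, int(p + 5 * sigma) + 1)
            out[lo:hi] += np.exp(-0.5 * ((grid[lo:hi] - p) / sigma) ** 2)
        return out
    raise ValueError(f"unknown kernel {kernel!r}")


def autocorrelation(
    smoothed: np.ndarray, max_lag: int, window: int = 0, kernel: str = "square"
) -> AutocorrelationCurve:
    """Finite-length autocorrelation of a smoothed sequence, C(0) = 1.

    ``C(x)`` averages ``X~(i) * X~(i+x)`` over the overlapping stretch and
    normalizes by the lag-zero value so that ``C(0) = 1``.
    """
    x = np.asarray(smoothed, dtype=float)
    length = x.size
    if max_lag >= length:
        raise ValueError(f"max_lag must be < sequence length {length}, got {max_lag}")
    if not np.any(x):
        raise ValueError("all-zero sequence: autocorrelation normalization undefined")
    n = 1 << int(np.ceil(np.log2(2 * length)))
    fx = np.fft.rfft(x, n)
    raw = np.fft.irfft(fx * np.conj(fx), n)[: max_lag + 1]
    lags = np.arange(max_lag + 1)
    values = raw / (length - lags)
    values = values / values[0]
    return AutocorrelationCurve(lags=lags, values=values, window=window, kernel=kernel)


def dft_of_autocorrelation(curve: AutocorrelationCurve, pad_factor: int = 4):
    """Fourier magnitude spectrum of the autocorrelation on a period axis."""
    return _dft_periods(curve.values, 1.0, pad_factor)
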