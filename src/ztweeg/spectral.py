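"""Spectral transforms and band energies.

The toolkit measures band activity from one of two spectra:

* the plain DFT magnitude ``|X[k]|``, ``X[k] = sum_n x[n] e^(-j 2 pi k n / N)``;
* the numerator of the group-delay function (NGD),
  ``NGD[k] = Re(X[k]) Re(Y[k]) + Im(X[k]) Im(Y[k])`` with ``Y`` the DFT of the
  time-weighted signal ``n * x[n]``.  Keeping only the numerator preserves the
  formant (peak) structure of the group delay while avoiding division by
  near-zero spectral magnitudes; NGD values may be negative.

High temporal resolution over short segments is obtained by zero-time
windowing (ZTW): multiplying the segment with the heavily low-pass-shaped
window ``psi[0] = 0``, ``psi[n] = 1 / (4 sin^2(pi n / 2N))``, whose zero first
sample forces the windowed signal's spectrum to have zero mean without
disturbing spectral peaks.

The energy of a band is the bin-index-weighted sum ``sum_k k * |S[k]|`` over
the band's bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .dataset import BandSpec
from .exceptions import ValidationError


@dataclass
class Spectrum:
    """A real-valued spectrum; bin ``k`` corresponds to ``k * fs / n_fft`` Hz."""

    values: np.ndarray  # shape (..., n_fft)
    n_fft: int
    fs: float
    kind: str  # "dft-magnitude" | "ngd"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape[-1] != self.n_fft:
            raise ValidationError("spectrum length disagrees with n_fft")


@dataclass
class ZtwWindow:
    """The zero-time window; ``samples[0] = 0`` and strictly decreasing after."""

    length: int
    samples: np.ndarray


def bandpass(x: np.ndarray, band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass (forward-backward Butterworth) of a time series.

    Accepts shape ``(..., samples)``; filters along the last axis.
    """
    if band.hi >= fs / 2:
        raise ValidationError(f"band edge {band.hi} Hz >= Nyquist ({fs / 2} Hz)")
    sos = _sig.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _check_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValidationError("signal must have at least 2 samples")
    return x


def dft_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """Magnitude DFT spectrum of ``x`` (last axis = time)."""
    x = _check_signal(x)
    X = np.fft.fft(x, axis=-1)
    return Spectrum(values=np.abs(X), n_fft=x.shape[-1], fs=fs, kind="dft-magnitude")


def ngd_spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """Numerator-group-delay spectrum of ``x`` (last axis = time).

    ``NGD = Re(X) Re(Y) + Im(X) Im(Y)`` where ``Y`` transforms ``n * x[n]``;
    no division is performed, so the result is well defined everywhere and
    bilinear in the signal (scaling ``x`` by ``c`` scales NGD by ``c^2``).
    """
    x = _check_signal(x)
    n = np.arange(x.shape[-1], dtype=float)
    X = np.fft.fft(x, axis=-1)
    Y = np.fft.fft(x * n, axis=-1)
    values = X.real * Y.real + X.imag * Y.imag
    return Spectrum(values=values, n_fft=x.shape[-1], fs=fs, kind="ngd")


def ztw_window(length: int) -> ZtwWindow:
    """Build the zero-time window of ``length`` samples (``N`` = ``length``)."""
    if length < 2:
        raise ValidationError("ZTW window needs length >= 2")
    n = np.arange(length, dtype=float)
    samples = np.zeros(length)
    samples[1:] = 1.0 / (4.0 * np.sin(np.pi * n[1:] / (2.0 * length)) ** 2)
    return ZtwWindow(length=length, samples=samples)


def apply_ztw(frame: np.ndarray, window: ZtwWindow) -> np.ndarray:
    """Multiply a frame (last axis = time) by the zero-time window.

    Because ``psi[0] = 0``, the DFT bins of the output sum to zero.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-1] != window.length:
        raise ValidationError(
            f"frame length {frame.shape[-1]} != window length {window.length}"
        )
    return frame * window.samples


def band_bins(band: BandSpec, n_fft: int, fs: float) -> tuple[int, int]:
    """Inclusive bin range ``[k_lo, k_hi]`` covering the band."""
    k_lo = int(round(band.lo * n_fft / fs))
    k_hi = int(round(band.hi * n_fft / fs))
    if k_hi >= n_fft or k_lo > k_hi:
        raise ValidationError(
            f"band {band.name!r} [{band.lo}, {band.hi}] Hz outside spectrum range"
        )
    return k_lo, k_hi


def band_energy(
    spec: Spectrum,
    band: BandSpec,
    use_magnitude: bool = True,
    weight_bins: bool = True,
) -> np.ndarray:
    """Bin-index-weighted band energy ``sum_k k * |S[k]|`` over the band bins.

    ``use_magnitude=False`` sums the raw (possibly signed) spectrum values
    instead; the default keeps energies non-negative for both spectrum kinds.
    ``weight_bins=False`` drops the leading bin-index weight (a plain band
    sum).  Vectorised over leading axes; returns a scalar for a 1-D spectrum.
    """
    k_lo, k_hi = band_bins(band, spec.n_fft, spec.fs)
    k = np.arange(k_lo, k_hi + 1, dtype=float) if weight_bins else 1.0
    vals = spec.values[..., k_lo : k_hi + 1]
    if use_magnitude:
        vals = np.abs(vals)
    out = np.sum(k * vals, axis=-1)
    return float(out) if out.ndim == 0 else out


def multiband_energy(
    spec: Spectrum,
    bands: Sequence[BandSpec],
    use_magnitude: bool = True,
    weight_bins: bool = True,
) -> np.ndarray:
    """Sum of :func:`band_energy` over the given bands."""
    if not bands:
        raise ValidationError("need at least one band")
    total = sum(
        band_energy(spec, b, use_magnitude=use_magnitude, weight_bins=weight_bins)
        for b in bands
    )
    return total


def frequency_axis(n_fft: int, fs: float) -> np.ndarray:
    """Frequency in Hz of every bin (bin k -> k*fs/N)."""
    return np.arange(n_fft) * fs / n_fft


def spectrum_to_csv(spec: Spectrum, path: str) -> None:
    """Export a spectrum as CSV: ``bin_hz`` plus one value column per channel."""
    import pandas as pd

    values = np.atleast_2d(spec.values)
    data = {"bin_hz": frequency_axis(spec.n_fft, spec.fs)}
    for c in range(values.shape[0]):
        data[f"ch{c}"] = values[c]
    pd.DataFrame(data).to_csv(path, index=False)
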