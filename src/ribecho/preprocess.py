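"""Trace preprocessing: t0 alignment, rectification, windowing, spectra.

Every classifier consumes one of two derived signals:

* the rectified time signal re-indexed so that sample 0 is the stimulus
  onset t0 (found from the large initial artifact), and
* the magnitude spectrum of an artifact-free time window, zero-padded to
  twice its length before the FFT so the frequency axis lands on a 6.25 kHz
  grid at the device's 25 MHz sampling rate.

Two distinct analysis windows are used downstream: time-domain features and
thresholding read [15, 107] µs after t0 (2300 samples at 25 MHz, i.e. whole
4 µs and 8 µs bins), while the frequency pipeline reads [15, 95] µs
(2000 samples, so the padded 4000-point transform has exactly 6.25 kHz
resolution and the 62.5/125 kHz feature bins tile it without remainder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .sim import RawTrace

#: Artifact exclusion boundary after t0 (s).
ARTIFACT_SPAN = 1.5e-5
#: Time-domain analysis window after t0 (s) — feeds time features/thresholds.
TIME_WINDOW = (1.5e-5, 1.07e-4)
#: Frequency-pipeline time window after t0 (s) — feeds the FFT.
FREQ_WINDOW = (1.5e-5, 9.5e-5)
#: Retained spectral band around the 715 kHz center frequency (Hz).
DEFAULT_BAND = (4.938e5, 9.313e5)
#: Search span for the stimulus artifact at the start of a raw trace (s).
T0_SEARCH_SPAN = 2.0e-5


@dataclass
class AlignedTrace:
    """Voltage trace re-indexed so sample 0 is stimulus onset."""

    voltage: np.ndarray
    sampling_rate: float
    t0_method: str  # "known" | "detected"

    @property
    def duration(self) -> float:
        return len(self.voltage) / self.sampling_rate


@dataclass
class Spectrum:
    """One-sided magnitude spectrum on a uniform grid starting at 0 Hz."""

    freqs: np.ndarray
    magnitude: np.ndarray
    resolution: float
    band: tuple[float, float] | None = None


def detect_t0(trace: RawTrace, artifact_fraction: float = 0.5) -> int:
    """Locate stimulus onset as the first threshold crossing of the artifact.

    Returns the first sample (within the opening 20 µs) where |v| reaches
    ``artifact_fraction`` of the local maximum absolute voltage.
    """
    if not 0.0 < artifact_fraction < 1.0:
        raise ConfigurationError("artifact_fraction must lie in (0, 1)")
    v = np.abs(trace.voltage)
    if v.size == 0:
        raise AlignmentError("empty trace")
    head = v[: max(1, int(round(T0_SEARCH_SPAN * trace.sampling_rate)))]
    peak = head.max()
    if peak <= 0.0:
        raise AlignmentError("no artifact found in the first 20 us")
    crossings = np.nonzero(head >= artifact_fraction * peak)[0]
    return int(crossings[0])


def align(trace: RawTrace, artifact_fraction: float = 0.5,
          use_known_t0: bool = False) -> AlignedTrace:
    """Shift a raw trace so its first sample is t0."""
    if use_known_t0:
        if trace.t0_index is None:
            raise AlignmentError("trace carries no known t0_index")
        t0, method = trace.t0_index, "known"
    else:
        t0, method = detect_t0(trace, artifact_fraction), "detected"
    return AlignedTrace(trace.voltage[t0:], trace.sampling_rate, method)


def rectify(aligned: AlignedTrace) -> AlignedTrace:
    """Elementwise absolute value (idempotent)."""
    return AlignedTrace(np.abs(aligned.voltage), aligned.sampling_rate,
                        aligned.t0_method)


def window_bounds(start_s: float, end_s: float, sampling_rate: float,
                  n_samples: int) -> tuple[int, int]:
    """Half-open sample interval [round(start*fs), round(end*fs))."""
    if not 0.0 <= start_s < end_s:
        raise ConfigurationError("require 0 <= start < end")
    i0 = int(round(start_s * sampling_rate))
    i1 = int(round(end_s * sampling_rate))
    if i1 > n_samples:
        raise ConfigurationError(
            f"window end {end_s * 1e6:.1f} us beyond trace "
            f"({n_samples / sampling_rate * 1e6:.1f} us)"
        )
    return i0, i1


def window_time(aligned: AlignedTrace, start_s: float, end_s: float,
                ) -> tuple[np.ndarray, int, int]:
    """Extract a time window; returns (segment, start_index, end_index)."""
    i0, i1 = window_bounds(start_s, end_s, aligned.sampling_rate,
                           len(aligned.voltage))
    return aligned.voltage[i0:i1], i0, i1


def envelope(rectified: np.ndarray, smooth_samples: int) -> np.ndarray:
    """Centered moving average of a rectified signal, length preserving.

    Edge samples are averaged over the available support only, so a
    constant signal maps to itself everywhere.
    """
    if smooth_samples < 1 or smooth_samples % 2 == 0:
        raise ConfigurationError("smooth_samples must be odd and >= 1")
    if smooth_samples == 1:
        return np.asarray(rectified, dtype=float).copy()
    x = np.asarray(rectified, dtype=float)
    kernel = np.ones(smooth_samples)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same")


def spectrum(
    aligned: AlignedTrace,
    window_start_s: float = FREQ_WINDOW[0],
    window_end_s: float = FREQ_WINDOW[1],
    band_lo_hz: float | None = None,
    band_hi_hz: float | None = None,
) -> Spectrum:
    """Zero-padded magnitude spectrum of an artifact-free time window.

    The un-rectified segment is padded with zeros equal to its own length
    (doubling it) before the FFT, halving the bin width to
    ``fs / (2 * segment_length)``. When a band is given, magnitudes outside
    [band_lo, band_hi] are zeroed but the axis keeps running from 0 Hz so
    bin indices stay global.
    """
    seg, _, _ = window_time(aligned, window_start_s, window_end_s)
    n = len(seg)
    if n == 0:
        raise ConfigurationError("empty spectrum window")
    nyquist = aligned.sampling_rate / 2.0
    if band_hi_hz is not None and band_hi_hz > nyquist:
        raise ConfigurationError(f"band_hi {band_hi_hz} Hz above Nyquist")

    padded = np.concatenate([seg, np.zeros(n)])
    mag = np.abs(np.fft.rfft(padded))
    resolution = aligned.sampling_rate / (2.0 * n)
    freqs = np.arange(mag.size) * resolution

    band = None
    if band_lo_hz is not None or band_hi_hz is not None:
        lo = 0.0 if band_lo_hz is None else band_lo_hz
        hi = nyquist if band_hi_hz is None else band_hi_hz
        if not lo < hi:
            raise ConfigurationError("band_lo must be below band_hi")
        mag = np.where((freqs >= lo) & (freqs <= hi), mag, 0.0)
        band = (lo, hi)

    return Spectrum(freqs=freqs, magnitude=mag, resolution=resolution, band=band)


def rectified_aligned(trace: RawTrace, artifact_fraction: float = 0.5,
                      use_known_t0: bool = False) -> AlignedTrace:
    """Convenience: align then rectify (the thresholds/features input)."""
    return rectify(align(trace, artifact_fraction, use_known_t0))
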