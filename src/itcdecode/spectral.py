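"""Spectral features of field-potential signals.

Total power: per 100-ms sliding window, the mean of the window periodogram
over its FFT frequency bins (10-Hz spacing for a 100-ms window; 101 bins
from 0 to 1000 Hz at a 2-kHz sampling rate, truncated at Nyquist below
that).  Band power: squared magnitude of a complex Morlet (Gabor) wavelet
convolution with carrier frequencies 4/12/24/40/80 Hz, Gaussian envelope
sigma equal to one carrier cycle period and tails truncated at 2 sigma; the
DC band is the mean squared raw voltage per window.  Band responses are
normalized to prestimulus (-200..0 ms) power and averaged over the
50-450-ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .features import (BAND_HZ, FeatureTable, STANDARD_SCHEME, WindowScheme,
                       feature_grid_meta)

RESPONSE_RANGE_MS = (50.0, 450.0)
BASELINE_RANGE_MS = (-200.0, 0.0)


def morlet_kernel(freq_hz: float, fs: float) -> np.ndarray:
    """Complex Morlet kernel, sigma = 1/f, truncated at +-2 sigma, unit energy."""
    if freq_hz <= 0:
        raise ValueError("band frequency must be positive")
    sigma = 1.0 / freq_hz
    half = int(round(2.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(-(t**2) / (2 * sigma**2)) * np.exp(2j * np.pi * freq_hz * t)
    k /= np.sqrt(np.sum(np.abs(k) ** 2) / fs)
    return k


def wavelet_power(signal: np.ndarray, freq_hz: float, fs: float) -> np.ndarray:
    """Squared magnitude of the Morlet convolution along the last axis."""
    x = np.asarray(signal, dtype=np.float64)
    k = morlet_kernel(freq_hz, fs)
    if x.shape[-1] < len(k):
        raise ValueError(
            f"epoch of {x.shape[-1]} samples shorter than the {len(k)}-sample "
            f"kernel support (4/f) at {freq_hz} Hz"
        )
    flat = x.reshape(-1, x.shape[-1])
    out = fftconvolve(flat, k[None, :], mode="same", axes=1)
    return (np.abs(out) ** 2).reshape(x.shape)


def total_power_band_grid(fs: float, width_ms: float = 100.0) -> np.ndarray:
    """Frequency bins (Hz) of the windowed FFT periodogram."""
    n = int(round(width_ms * fs / 1000.0))
    return np.fft.rfftfreq(n, d=1.0 / fs)


def _window_segments(epochs: np.ndarray, fs: float, epoch_t0_ms: float,
                     scheme: WindowScheme) -> list[np.ndarray]:
    slices = scheme.sample_slices(fs, epoch_t0_ms)
    for sl in slices:
        if sl.stop > epochs.shape[-1]:
            raise ValueError("window extends past epoch end")
    return [epochs[..., sl] for sl in slices]


def total_power_features(
    epochs: np.ndarray,
    fs: float,
    trial_meta: pd.DataFrame,
    epoch_t0_ms: float = -50.0,
    scheme: WindowScheme = STANDARD_SCHEME,
) -> FeatureTable:
    """Mean periodogram power ("total power") per channel and window.

    ``epochs`` is (trials, channels, samples) starting at ``epoch_t0_ms``
    relative to stimulus onset.  The band grid covers the window's FFT bins;
    below a 2-kHz sampling rate it is truncated at Nyquist (flagged in the
    feature metadata).
    """
    if scheme.width_ms < 100.0:
        raise ValueError("window shorter than 100 ms")
    n_trials, n_ch, _ = epochs.shape
    w = int(round(scheme.width_ms * fs / 1000.0))
    segs = _window_segments(epochs, fs, epoch_t0_ms, scheme)
    cols = []
    for seg in segs:
        spec = np.abs(np.fft.rfft(seg, axis=-1)) ** 2 / w
        cols.append(spec.mean(axis=-1))  # mean over frequency bands
    # (trials, channels, windows) -> channel-major feature order
    values = np.stack(cols, axis=-1).reshape(n_trials, n_ch * scheme.n_windows)
    meta = feature_grid_meta(n_ch, scheme, band="total")
    meta.attrs["band_grid_hz"] = total_power_band_grid(fs, scheme.width_ms).tolist()
    meta.attrs["truncated_at_nyquist"] = bool(fs < 2000.0)
    return FeatureTable(values, meta, trial_meta)


def band_power_features(
    epochs: np.ndarray,
    band: str,
    fs: float,
    trial_meta: pd.DataFrame,
    epoch_t0_ms: float,
    scheme: WindowScheme = STANDARD_SCHEME,
) -> FeatureTable:
    """Windowed band-power features for one wavelet band (or DC).

    For wavelet bands ``epochs`` should extend beyond the window span by the
    kernel half-support so edge effects do not reach the analysis windows.
    """
    n_trials, n_ch, _ = epochs.shape
    if band == "DC":
        power = np.asarray(epochs, dtype=np.float64) ** 2
    else:
        power = wavelet_power(epochs, BAND_HZ[band], fs)
    segs = _window_segments(power, fs, epoch_t0_ms, scheme)
    values = np.stack([s.mean(axis=-1) for s in segs], axis=-1)
    values = values.reshape(n_trials, n_ch * scheme.n_windows)
    return FeatureTable(values, feature_grid_meta(n_ch, scheme, band=band),
                        trial_meta)


@dataclass
class BandResponse:
    """Per channel x trial normalized band response (50-450-ms mean)."""

    values: np.ndarray  # (trials, channels)
    band: str
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("band response must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def response_bins(scheme: WindowScheme = STANDARD_SCHEME,
                  lo_ms: float = RESPONSE_RANGE_MS[0],
                  hi_ms: float = RESPONSE_RANGE_MS[1]) -> np.ndarray:
    """Window indices whose centers fall in [lo, hi) ms (8 of the 12)."""
    centers = scheme.centers_ms
    return np.flatnonzero((centers >= lo_ms) & (centers < hi_ms))


def normalize_and_bin(
    power: np.ndarray,
    fs: float,
    trial_meta: pd.DataFrame,
    band: str,
    epoch_t0_ms: float,
    scheme: WindowScheme = STANDARD_SCHEME,
    baseline_mode: str = "session",
) -> BandResponse:
    """Prestimulus-normalized, binned band response.

    ``power`` is a (trials, channels, samples) power time series starting at
    ``epoch_t0_ms``.  Power is divided by the mean prestimulus (-200..0 ms)
    power of the same channel — averaged over the session's trials by
    default, or per trial with ``baseline_mode='trial'`` — then averaged over
    the analysis bins in the 50-450-ms range.
    """
    if epoch_t0_ms > BASELINE_RANGE_MS[0]:
        raise ValueError("epoch must include the -200..0 ms prestimulus period")
    b0 = int(round((BASELINE_RANGE_MS[0] - epoch_t0_ms) * fs / 1000.0))
    b1 = int(round((BASELINE_RANGE_MS[1] - epoch_t0_ms) * fs / 1000.0))
    baseline_t = power[:, :, b0:b1].mean(axis=-1)  # (trials, channels)
    if baseline_mode == "session":
        baseline = baseline_t.mean(axis=0, keepdims=True)
    elif baseline_mode == "trial":
        baseline = baseline_t
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if np.any(baseline <= 0):
        raise ValueError("zero baseline power")
    normalized = power / baseline[..., None]
    segs = _window_segments(normalized, fs, epoch_t0_ms, scheme)
    bins = np.stack([s.mean(axis=-1) for s in segs], axis=-1)
    resp = bins[:, :, response_bins(scheme)].mean(axis=-1)
    return BandResponse(values=resp, band=band, trial_meta=trial_meta)
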