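"""Convenience feature extraction from whole sessions.

Thin wrappers that cut correctly padded epochs out of a :class:`Session`
and call the windowed feature operations, so the pipeline, CLI, and tests
share one code path.
"""

from __future__ import annotations

import numpy as np

from .features import (FeatureTable, STANDARD_SCHEME, WindowScheme, BAND_HZ,
                       extract_epochs, trial_metadata)
from .phase import PhaseSample, theta_phase_at
from .simulate import Session
from .spectral import (BandResponse, band_power_features, normalize_and_bin,
                       total_power_features, wavelet_power)
from .spikes import SpikeTrain, window_spike_rates
from .stimuli import StimulusSet


def _epoch_bounds(scheme: WindowScheme, band: str | None) -> tuple[float, float]:
    """Epoch bounds (ms) covering all windows, baseline, and kernel support."""
    end = float(scheme.starts_ms[-1] + scheme.width_ms)
    pad = 0.0
    if band is not None and band != "DC":
        pad = 2000.0 / BAND_HZ[band]  # 2 sigma = 2 cycle periods, in ms
    t0 = min(-50.0 - pad, -250.0)  # always include the -200..0 ms baseline
    return t0, end + pad


def spike_trains(session: Session) -> list[SpikeTrain]:
    return [SpikeTrain(ch, ts) for ch, ts in enumerate(session.spikes)]


def spike_rate_features(session: Session, stimuli: StimulusSet,
                        scheme: WindowScheme = STANDARD_SCHEME) -> FeatureTable:
    return window_spike_rates(spike_trains(session), session.trials, stimuli,
                              session.sample_rate_hz, scheme)


def total_power_from_session(
    session: Session, stimuli: StimulusSet, modality: str,
    scheme: WindowScheme = STANDARD_SCHEME,
) -> FeatureTable:
    t0, t1 = _epoch_bounds(scheme, band=None)
    epochs = extract_epochs(session.signal(modality), session.onsets,
                            session.sample_rate_hz, t0, t1)
    return total_power_features(epochs, session.sample_rate_hz,
                                trial_metadata(session.trials, stimuli),
                                epoch_t0_ms=t0, scheme=scheme)


def band_features_from_session(
    session: Session, stimuli: StimulusSet, modality: str, band: str,
    scheme: WindowScheme = STANDARD_SCHEME,
) -> FeatureTable:
    t0, t1 = _epoch_bounds(scheme, band)
    epochs = extract_epochs(session.signal(modality), session.onsets,
                            session.sample_rate_hz, t0, t1)
    return band_power_features(epochs, band, session.sample_rate_hz,
                               trial_metadata(session.trials, stimuli),
                               epoch_t0_ms=t0, scheme=scheme)


def band_response_from_session(
    session: Session, stimuli: StimulusSet, modality: str, band: str,
    scheme: WindowScheme = STANDARD_SCHEME,
    baseline_mode: str = "session",
    response_window_ms: tuple[float, float] | None = None,
) -> BandResponse:
    """Prestimulus-normalized 50-450-ms band response per channel x trial.

    ``response_window_ms`` overrides the binning range (e.g. the 100-200-ms
    early window or 300-500-ms late window of the selectivity maps).
    """
    t0, t1 = _epoch_bounds(scheme, band)
    fs = session.sample_rate_hz
    epochs = extract_epochs(session.signal(modality), session.onsets, fs, t0, t1)
    if band == "DC":
        power = np.asarray(epochs) ** 2
    else:
        power = wavelet_power(epochs, BAND_HZ[band], fs)
    meta = trial_metadata(session.trials, stimuli)
    if response_window_ms is None:
        return normalize_and_bin(power, fs, meta, band, epoch_t0_ms=t0,
                                 scheme=scheme, baseline_mode=baseline_mode)
    # direct window mean for custom early/late map windows
    b0 = int(round((-200.0 - t0) * fs / 1000.0))
    b1 = int(round((0.0 - t0) * fs / 1000.0))
    baseline = power[:, :, b0:b1].mean(axis=-1)
    if baseline_mode == "session":
        baseline = baseline.mean(axis=0, keepdims=True)
    if np.any(baseline <= 0):
        raise ValueError("zero baseline power")
    e0 = int(round((response_window_ms[0] - t0) * fs / 1000.0))
    e1 = int(round((response_window_ms[1] - t0) * fs / 1000.0))
    resp = power[:, :, e0:e1].mean(axis=-1) / baseline
    return BandResponse(values=resp, band=band, trial_meta=meta)


def band_power_epochs(
    session: Session, stimuli: StimulusSet, modality: str, band: str,
    scheme: WindowScheme = STANDARD_SCHEME,
) -> tuple[np.ndarray, float]:
    """Raw band-power time series epochs and their epoch start (ms)."""
    t0, t1 = _epoch_bounds(scheme, band)
    fs = session.sample_rate_hz
    epochs = extract_epochs(session.signal(modality), session.onsets, fs, t0, t1)
    power = (np.asarray(epochs) ** 2 if band == "DC"
             else wavelet_power(epochs, BAND_HZ[band], fs))
    return power, t0


def theta_phase_from_session(
    session: Session, stimuli: StimulusSet, modality: str,
    probe_ms: float = 75.0,
) -> PhaseSample:
    t0, t1 = _epoch_bounds(STANDARD_SCHEME, "theta4")
    epochs = extract_epochs(session.signal(modality), session.onsets,
                            session.sample_rate_hz, t0, t1)
    return theta_phase_at(epochs, session.sample_rate_hz, t0,
                          trial_metadata(session.trials, stimuli),
                          probe_ms=probe_ms)
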