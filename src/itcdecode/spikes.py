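"""Multi-unit spike processing.

Threshold-crossing detection on band-passed signals, kernel-optimized spike
density functions (Gaussian kernel whose bandwidth minimizes the
Shimazaki-Shinomoto MISE-based cost), visual-responsiveness screening by
Kolmogorov-Smirnov test with Bonferroni correction over stimuli, and
windowed spike-rate feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import (FeatureTable, STANDARD_SCHEME, WindowScheme,
                       feature_grid_meta, trial_metadata)

DEFAULT_THRESHOLD_MULTIPLIER = 3.7
DEAD_TIME_S = 1e-3


@dataclass
class SpikeTrain:
    channel_id: int
    timestamps: np.ndarray  # seconds, strictly increasing
    detection_threshold_multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


def detect_spikes(
    wideband: np.ndarray,
    fs: float,
    multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
    channel_id: int = 0,
) -> SpikeTrain:
    """Detect upward threshold crossings at ``multiplier`` x signal SD.

    One timestamp per upward crossing of the positive threshold, with a 1-ms
    dead time between accepted events.  Raises on a flat (zero-variance)
    signal.
    """
    x = np.asarray(wideband, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        raise ValueError("flat signal")
    thr = multiplier * sd
    above = x > thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    dead = int(round(DEAD_TIME_S * fs))
    kept: list[int] = []
    last = -dead - 1
    for idx in crossings:
        if idx - last > dead:
            kept.append(idx)
            last = idx
    return SpikeTrain(channel_id, np.asarray(kept, dtype=np.float64) / fs,
                      multiplier)


def _ss_cost(spike_times: np.ndarray, w: float) -> float:
    """Shimazaki-Shinomoto MISE cost of Gaussian-kernel bandwidth ``w``.

    C(w) = n / (2 sqrt(pi) w) + sum_{i != j} [ phi_{sqrt(2) w}(dij)
                                               - 2 phi_w(dij) ]
    where phi_s is the centered normal density with SD s.
    """
    n = len(spike_times)
    d = spike_times[:, None] - spike_times[None, :]
    off = ~np.eye(n, dtype=bool)
    dij = d[off]
    term = (np.exp(-dij**2 / (4 * w**2)) / (2 * np.sqrt(np.pi) * w)
            - 2 * np.exp(-dij**2 / (2 * w**2)) / (np.sqrt(2 * np.pi) * w))
    return n / (2 * np.sqrt(np.pi) * w) + term.sum()


def optimize_bandwidth(spike_times: np.ndarray,
                       n_grid: int = 40) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimize the MISE cost over a log-spaced bandwidth grid.

    Returns (best bandwidth, grid, costs).
    """
    t = np.asarray(spike_times, dtype=np.float64)
    span = t.max() - t.min()
    isi = np.diff(np.sort(t))
    lo = max(np.min(isi[isi > 0], initial=span / 100) / 2, span * 1e-4)
    grid = np.geomspace(lo, span, n_grid)
    costs = np.array([_ss_cost(t, w) for w in grid])
    return float(grid[np.argmin(costs)]), grid, costs


def spike_density(
    train: SpikeTrain,
    window: tuple[float, float],
    dt: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian-kernel spike density function with optimized bandwidth.

    Returns (time grid, rate in spikes/s, bandwidth).  The rate integrates to
    the spike count in the window.  With fewer than 2 spikes the bandwidth
    falls back to a quarter of the window span.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    grid = np.arange(t0, t1, dt)
    ts = train.timestamps
    ts = ts[(ts >= t0) & (ts < t1)]
    if len(ts) == 0:
        return grid, np.zeros_like(grid), (t1 - t0) / 4.0
    if len(ts) == 1 or np.ptp(ts) == 0:
        bw = (t1 - t0) / 4.0
    else:
        bw, _, _ = optimize_bandwidth(ts)
    rate = np.zeros_like(grid)
    for s in ts:
        rate += np.exp(-((grid - s) ** 2) / (2 * bw**2))
    rate /= np.sqrt(2 * np.pi) * bw
    return grid, rate, bw


def responsiveness_test(
    rates_pre,
    rates_evoked,
    n_stimuli: int | None = None,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Visual-responsiveness screen by per-stimulus KS test.

    ``rates_pre`` / ``rates_evoked`` are per-stimulus sequences of samples
    (or single sample arrays, treated as one stimulus).  Each stimulus's
    prestimulus and evoked distributions are compared with a two-sample
    Kolmogorov-Smirnov test; p-values are Bonferroni-corrected by the number
    of stimuli.  Responsive iff the smallest corrected p < alpha.

    Returns (responsive, smallest corrected p-value).
    """
    if np.isscalar(rates_pre[0]):
        rates_pre, rates_evoked = [np.asarray(rates_pre)], [np.asarray(rates_evoked)]
    if len(rates_pre) != len(rates_evoked):
        raise ValueError("mismatched trial structure")
    if n_stimuli is None:
        n_stimuli = len(rates_pre)
    p_min = 1.0
    for pre, ev in zip(rates_pre, rates_evoked):
        pre, ev = np.asarray(pre), np.asarray(ev)
        if len(pre) < 3 or len(ev) < 3:
            raise ValueError("need >= 3 samples per side")
        if np.array_equal(np.sort(pre), np.sort(ev)):
            p = 1.0
        else:
            p = stats.ks_2samp(pre, ev, method="auto").pvalue
        p_min = min(p_min, min(p * n_stimuli, 1.0))
    return bool(p_min < alpha), float(p_min)


def window_spike_rates(
    trains: list[SpikeTrain] | SpikeTrain,
    trials: pd.DataFrame,
    stimuli,
    fs: float,
    scheme: WindowScheme = STANDARD_SCHEME,
) -> FeatureTable:
    """Windowed spike-rate features (count / window width, spikes/s).

    One feature per channel per window (12 windows under the standard
    -50..600-ms scheme).
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    onsets_s = trials["onset_sample"].to_numpy() / fs
    starts = scheme.starts_ms / 1000.0
    width = scheme.width_ms / 1000.0
    n_trials = len(onsets_s)
    values = np.empty((n_trials, len(trains) * scheme.n_windows))
    col = 0
    for train in trains:
        ts = train.timestamps
        for s in starts:
            lo = np.searchsorted(ts, onsets_s + s)
            hi = np.searchsorted(ts, onsets_s + s + width)
            values[:, col] = (hi - lo) / width
            col += 1
    meta = feature_grid_meta(len(trains), scheme, band="rate")
    meta["channel"] = np.repeat([t.channel_id for t in trains], scheme.n_windows)
    return FeatureTable(values, meta, trial_metadata(trials, stimuli))
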