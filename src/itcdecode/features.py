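"""Feature containers and epoch/window bookkeeping.

A :class:`FeatureTable` is a trials x features matrix with per-feature tags
(channel, time window, frequency band) and per-trial tags (stimulus id and
hierarchy labels), the common currency between feature extraction, decoding,
and the shuffle controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import LEVELS, StimulusSet

#: band labels used by feature tagging
BAND_NAMES = ("DC", "theta4", "alpha12", "beta24", "lowgamma40", "highgamma80")
BAND_HZ = {"theta4": 4.0, "alpha12": 12.0, "beta24": 24.0,
           "lowgamma40": 40.0, "highgamma80": 80.0}


@dataclass(frozen=True)
class WindowScheme:
    """Sliding analysis windows relative to stimulus onset (ms)."""

    t_start_ms: float = -50.0
    t_stop_ms: float = 600.0
    width_ms: float = 100.0
    step_ms: float = 50.0
    #: override window count (used by the 25-point timecourse grid, whose
    #: final windows extend past t_stop into the inter-trial gap)
    n_override: int | None = None

    @property
    def starts_ms(self) -> np.ndarray:
        if self.n_override is not None:
            n = self.n_override
        else:
            n = int(round((self.t_stop_ms - self.t_start_ms - self.width_ms)
                          / self.step_ms)) + 1
        return self.t_start_ms + self.step_ms * np.arange(max(n, 1))

    @property
    def n_windows(self) -> int:
        return len(self.starts_ms)

    @property
    def centers_ms(self) -> np.ndarray:
        return self.starts_ms + self.width_ms / 2.0

    def sample_slices(self, fs: float, epoch_t0_ms: float) -> list[slice]:
        """Sample slices of each window within an epoch starting at epoch_t0."""
        out = []
        w = int(round(self.width_ms * fs / 1000.0))
        for s in self.starts_ms:
            i0 = int(round((s - epoch_t0_ms) * fs / 1000.0))
            if i0 < 0:
                raise ValueError("window precedes epoch start")
            out.append(slice(i0, i0 + w))
        return out


#: the standard 12-window scheme: -50..600 ms, 100-ms windows, 50-ms shift
STANDARD_SCHEME = WindowScheme()
#: the timecourse scheme: same windows slid by 25 ms (25 time points)
TIMECOURSE_SCHEME = WindowScheme(step_ms=25.0, n_override=25)


def extract_epochs(
    signal: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    t0_ms: float,
    t1_ms: float,
) -> np.ndarray:
    """Cut (n_trials, n_channels, L) epochs from a (channels, samples) array."""
    i0 = int(round(t0_ms * fs / 1000.0))
    i1 = int(round(t1_ms * fs / 1000.0))
    L = i1 - i0
    n_samples = signal.shape[1]
    out = np.empty((len(onsets), signal.shape[0], L), dtype=np.float64)
    for k, on in enumerate(np.asarray(onsets)):
        a = on + i0
        if a < 0 or a + L > n_samples:
            raise ValueError(f"trial at sample {on} too close to signal edge")
        out[k] = signal[:, a:a + L]
    return out


class FeatureTable:
    """Trials x features matrix with feature and trial metadata.

    ``feature_meta`` columns: channel (int), window (int), band (str).
    ``trial_meta`` columns: stimulus_id plus the four hierarchy labels.
    """

    def __init__(self, values: np.ndarray, feature_meta: pd.DataFrame,
                 trial_meta: pd.DataFrame):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if len(feature_meta) != values.shape[1]:
            raise ValueError("feature_meta length mismatch")
        if len(trial_meta) != values.shape[0]:
            raise ValueError("trial_meta length mismatch")
        if not np.isfinite(values).all():
            raise ValueError("feature values must be finite")
        self.values = values
        self.feature_meta = feature_meta.reset_index(drop=True)
        self.trial_meta = trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels(self, level: str) -> np.ndarray:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        return self.trial_meta[level].to_numpy()

    def subset_trials(self, index: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.values[index],
                            self.feature_meta,
                            self.trial_meta.iloc[np.asarray(index)])

    def subset_features(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(self.values[:, mask],
                            self.feature_meta.iloc[mask]
                            if mask.dtype == bool or mask.ndim == 1
                            else self.feature_meta,
                            self.trial_meta)

    def select(self, band: str | None = None,
               window: int | None = None) -> "FeatureTable":
        m = np.ones(self.n_features, dtype=bool)
        if band is not None:
            m &= (self.feature_meta["band"] == band).to_numpy()
        if window is not None:
            m &= (self.feature_meta["window"] == window).to_numpy()
        if not m.any():
            raise ValueError("selection matches no features")
        return self.subset_features(m)

    @staticmethod
    def concat_features(tables: list["FeatureTable"]) -> "FeatureTable":
        base = tables[0].trial_meta
        for t in tables[1:]:
            if not t.trial_meta["stimulus_id"].equals(base["stimulus_id"]):
                raise ValueError("trial structures differ")
        return FeatureTable(
            np.hstack([t.values for t in tables]),
            pd.concat([t.feature_meta for t in tables], ignore_index=True),
            base,
        )

    # -- plain-text serialization (CSV + JSON sidecar) ----------------------
    def to_files(self, prefix: str) -> None:
        df = pd.concat(
            [self.trial_meta.reset_index(drop=True),
             pd.DataFrame(self.values,
                          columns=[f"f{i}" for i in range(self.n_features)])],
            axis=1,
        )
        df.to_csv(f"{prefix}.csv", index=False)
        with open(f"{prefix}.meta.json", "w") as fh:
            json.dump(self.feature_meta.to_dict(orient="list"), fh)

    @staticmethod
    def from_files(prefix: str) -> "FeatureTable":
        df = pd.read_csv(f"{prefix}.csv")
        with open(f"{prefix}.meta.json") as fh:
            meta = pd.DataFrame(json.load(fh))
        trial_cols = [c for c in df.columns if not c.startswith("f")]
        fcols = [c for c in df.columns if c.startswith("f")]
        return FeatureTable(df[fcols].to_numpy(), meta, df[trial_cols])


def trial_metadata(trials: pd.DataFrame, stimuli: StimulusSet) -> pd.DataFrame:
    """Expand a trial table with the four hierarchy label columns."""
    rows = []
    for sid in trials["stimulus_id"]:
        s = stimuli[sid]
        rows.append({"stimulus_id": sid, "coarse": s.coarse,
                     "species": s.species, "view": s.view,
                     "identity": s.identity})
    return pd.DataFrame(rows)


def feature_grid_meta(n_channels: int, scheme: WindowScheme,
                      band: str) -> pd.DataFrame:
    """Feature tags for a channels x windows grid, channel-major order."""
    ch = np.repeat(np.arange(n_channels), scheme.n_windows)
    win = np.tile(np.arange(scheme.n_windows), n_channels)
    return pd.DataFrame({"channel": ch, "window": win, "band": band})
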