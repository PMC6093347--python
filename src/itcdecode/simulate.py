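"""Session simulator: continuous LFP/ECoG signals plus spike trains.

Signal model
------------
Cortical sources on a fine lattice emit two stimulus-driven components per
trial: an evoked theta (4 Hz) oscillation phase-locked to stimulus onset up
to a per-category phase jitter, and an induced gamma (80 Hz) oscillation
whose amplitude is category-tuned but whose phase is random per source and
trial.  A recorded channel is a Gaussian-kernel spatial average of source
activity around its grid coordinate: the averaging radius is small for
MUA-like pickup, intermediate for penetrating-electrode LFP, and large for
surface ECoG.  Shared (cross-channel) and private white noise are added.
Each channel's spike train is an inhomogeneous Poisson process whose rate
follows that channel's local induced-gamma envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .stimuli import NA, Stimulus, StimulusSet
from .tuning import TuningMaps

THETA_HZ = 4.0
GAMMA_HZ = 80.0
#: epoch of stimulus-driven activity after onset (s)
RESPONSE_SPAN_S = 0.65
# margins sized so the theta wavelet kernel (+-2 sigma = +-500 ms) is fully
# supported around the -50..650-ms analysis span of every trial
PRE_MARGIN_S = 0.8
POST_MARGIN_S = 1.3


@dataclass
class Session:
    """One simulated recording session."""

    lfp: np.ndarray          # (n_channels, n_samples) float32
    ecog: np.ndarray         # (n_channels, n_samples) float32
    spikes: list             # per channel: float64 spike times (s), increasing
    trials: pd.DataFrame     # columns: onset_sample (int), stimulus_id (str)
    geometry_lfp: np.ndarray   # (n_channels, 2) mm
    geometry_ecog: np.ndarray  # offset by half a pitch from the LFP grid
    sample_rate_hz: float
    config_json: str = ""
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def onsets(self) -> np.ndarray:
        return self.trials["onset_sample"].to_numpy()

    def signal(self, modality: str) -> np.ndarray:
        if modality == "lfp":
            return self.lfp
        if modality == "ecog":
            return self.ecog
        raise ValueError(f"unknown modality {modality!r}")

    def validate(self) -> None:
        fs = self.sample_rate_hz
        on = self.onsets
        if (on < int(0.2 * fs)).any() or (on > self.n_samples - int(0.6 * fs)).any():
            raise ValueError("trial onset violates pre/post signal margins")
        for k, st in enumerate(self.spikes):
            if np.any(np.diff(st) <= 0):
                raise ValueError(f"spike timestamps not strictly increasing on ch{k}")


def grid_positions(config: SimConfig, offset_mm: float = 0.0) -> np.ndarray:
    """Channel coordinates of the recording grid (row-major channel order)."""
    rows, cols = config.grid_rows, config.grid_cols
    xs = np.arange(cols) * config.pitch_mm + offset_mm
    ys = np.arange(rows) * config.pitch_mm + offset_mm
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _pickup_weights(channel_pos: np.ndarray, source_pos: np.ndarray,
                    radius_mm: float) -> np.ndarray:
    """Row-normalized Gaussian pickup: channel = weighted source average."""
    d2 = ((channel_pos[:, None, :] - source_pos[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * radius_mm**2))
    return w / w.sum(axis=1, keepdims=True)


def _theta_envelope(t: np.ndarray) -> np.ndarray:
    return np.exp(-((t - 0.15) ** 2) / (2 * 0.10**2))


def _gamma_envelope(t: np.ndarray) -> np.ndarray:
    rise = 1.0 / (1.0 + np.exp(-(t - 0.12) / 0.02))
    fall = 1.0 / (1.0 + np.exp((t - 0.48) / 0.04))
    return rise * fall


def _phase_jitter_sd(config: SimConfig, stim: Stimulus) -> float:
    table = config.phase_jitter_by_category
    for level in ("view", "identity", "species", "coarse"):
        lab = stim.label(level)
        if lab != NA and lab in table:
            return float(table[lab])
    return float(table.get("default", 0.0))


def _trial_schedule(config: SimConfig, stimuli: StimulusSet,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, int]:
    order = np.repeat(np.arange(len(stimuli)), config.n_trials_per_stimulus)
    rng.shuffle(order)
    fs = config.sample_rate_hz
    onset = PRE_MARGIN_S
    onsets = []
    for _ in order:
        onsets.append(int(round(onset * fs)))
        iti = rng.uniform(*config.iti_ms_range) / 1000.0
        onset += config.stim_duration_ms / 1000.0 + iti
    n_samples = int(round((onset + POST_MARGIN_S) * fs))
    ids = [stimuli.stimuli[k].stimulus_id for k in order]
    return pd.DataFrame({"onset_sample": onsets, "stimulus_id": ids}), n_samples


def _sorted_strict(times: np.ndarray) -> np.ndarray:
    times = np.sort(times)
    # break exact ties so timestamps are strictly increasing
    while np.any(np.diff(times) <= 0):
        dup = np.flatnonzero(np.diff(times) <= 0) + 1
        times[dup] += 1e-9
        times = np.sort(times)
    return times


def simulate_session(
    config: SimConfig,
    stimuli: StimulusSet,
    maps: TuningMaps,
    max_duration_s: float | None = None,
) -> Session:
    """Simulate one session; bit-identical for identical (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    fs = config.sample_rate_hz
    trials, n_samples = _trial_schedule(config, stimuli, rng)
    if max_duration_s is not None and n_samples > max_duration_s * fs:
        raise ValueError(
            f"trial schedule needs {n_samples / fs:.1f}s but only "
            f"{max_duration_s:.1f}s of signal is allowed"
        )

    pos_lfp = grid_positions(config)
    pos_ecog = grid_positions(config, offset_mm=config.pitch_mm / 2.0)
    w_lfp = _pickup_weights(pos_lfp, maps.positions, config.r_lfp_mm)
    w_ecog = _pickup_weights(pos_ecog, maps.positions, config.r_ecog_mm)
    w_mua = _pickup_weights(pos_lfp, maps.positions, config.r_mua_mm)

    nch = config.n_channels
    lfp = rng.standard_normal((nch, n_samples), dtype=np.float32)
    lfp *= np.float32(config.private_noise_sd)
    ecog = rng.standard_normal((nch, n_samples), dtype=np.float32)
    ecog *= np.float32(config.private_noise_sd)
    for arr in (lfp, ecog):
        shared = rng.standard_normal(n_samples, dtype=np.float32)
        arr += np.float32(config.shared_noise_sd) * shared[None, :]

    L = int(round(RESPONSE_SPAN_S * fs))
    t = np.arange(L) / fs
    env_th = _theta_envelope(t)
    env_g = _gamma_envelope(t)
    cos_th, sin_th = np.cos(2 * np.pi * THETA_HZ * t), np.sin(2 * np.pi * THETA_HZ * t)
    cos_g, sin_g = np.cos(2 * np.pi * GAMMA_HZ * t), np.sin(2 * np.pi * GAMMA_HZ * t)
    n_src = maps.n_sources

    # per-channel extra spike-rate envelopes accumulated per trial
    rate_extra = np.zeros((len(trials), nch))

    for k, row in enumerate(trials.itertuples(index=False)):
        stim = stimuli[row.stimulus_id]
        i0 = row.onset_sample
        sl = slice(i0, i0 + L)

        # evoked theta: phase-locked up to per-category source-level jitter
        amp_th = config.evoked_theta_amp * maps.source_amplitude("theta", stim)
        amp_th = amp_th * np.exp(rng.normal(0.0, config.source_noise_sd, n_src))
        jitter = rng.normal(0.0, _phase_jitter_sd(config, stim), n_src)
        c, s = amp_th * np.cos(jitter), amp_th * np.sin(jitter)
        for arr, w in ((lfp, w_lfp), (ecog, w_ecog)):
            u, v = w @ c, w @ s
            arr[:, sl] += (
                np.outer(u, env_th * cos_th) - np.outer(v, env_th * sin_th)
            ).astype(np.float32)

        # induced gamma: category-tuned amplitude, trial/source-random phase
        amp_g = config.induced_gamma_amp * maps.source_amplitude("gamma", stim)
        amp_g = amp_g * np.exp(rng.normal(0.0, config.source_noise_sd, n_src))
        phi = rng.uniform(0.0, 2 * np.pi, n_src)
        c, s = amp_g * np.cos(phi), amp_g * np.sin(phi)
        for arr, w in ((lfp, w_lfp), (ecog, w_ecog)):
            u, v = w @ c, w @ s
            arr[:, sl] += (
                np.outer(u, env_g * cos_g) - np.outer(v, env_g * sin_g)
            ).astype(np.float32)

        # local gamma envelope drives spiking (envelope mixing, tight pickup)
        rate_extra[k] = config.spike_gain_hz * (w_mua @ amp_g)

    # spikes: homogeneous baseline + inhomogeneous stimulus-driven extra
    duration = n_samples / fs
    cum_env = np.concatenate([[0.0], np.cumsum(env_g)]) / max(env_g.sum(), 1e-12)
    env_integral = env_g.sum() / fs  # s
    spikes = []
    for ch in range(nch):
        n_base = rng.poisson(config.base_rate_hz * duration)
        times = [rng.uniform(0.0, duration, n_base)]
        for k, row in enumerate(trials.itertuples(index=False)):
            lam = rate_extra[k, ch] * env_integral
            n_ev = rng.poisson(lam)
            if n_ev:
                u = rng.uniform(0.0, 1.0, n_ev)
                idx = np.searchsorted(cum_env, u)
                times.append(row.onset_sample / fs + idx / fs)
        spikes.append(_sorted_strict(np.concatenate(times)))

    session = Session(
        lfp=lfp, ecog=ecog, spikes=spikes, trials=trials,
        geometry_lfp=pos_lfp, geometry_ecog=pos_ecog,
        sample_rate_hz=fs, config_json=config.to_json(), seed=config.seed,
    )
    session.validate()
    return session


def discriminant_contrast(
    config: SimConfig,
    stimuli: StimulusSet,
    maps: TuningMaps,
    band: str,
    level: str,
    pair: tuple[str, str],
    modality: str,
) -> np.ndarray:
    """Per-channel category-discriminating component of the mixed amplitude.

    Returns, for each channel, the spatial average (at the modality's pickup
    radius) of the difference in mean source amplitude between the two
    categories — the generator-internal quantity whose cross-channel variance
    measures how much discriminative signal survives spatial summation.
    """
    radius = {"mua": config.r_mua_mm, "lfp": config.r_lfp_mm,
              "ecog": config.r_ecog_mm}[modality]
    offset = config.pitch_mm / 2.0 if modality == "ecog" else 0.0
    w = _pickup_weights(grid_positions(config, offset), maps.positions, radius)
    means = []
    for label in pair:
        amps = [maps.source_amplitude(band, s)
                for s in stimuli.with_label(level, label)]
        means.append(np.mean(amps, axis=0))
    return w @ (means[0] - means[1])
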