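"""Theta phase-locking across channels.

At a fixed post-stimulus probe time (75 ms by default — where the
difference between LFP- and ECoG-based decoding time courses changes
fastest), each channel's theta (4 Hz) wavelet phase is a unit vector in the
complex plane; the phase-locking value (PLV) of a trial is the length of
the mean resultant of these channel vectors, 1 for perfect cross-channel
phase alignment and 0 for uniform dispersion.  PLV distributions are
compared across category members with rank-based tests (Mann-Whitney U for
the two species; Kruskal-Wallis plus Dunn's pairwise post-hoc with
Bonferroni correction for the three facial views).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import morlet_kernel

DEFAULT_PROBE_MS = 75.0
THETA_HZ = 4.0


@dataclass
class PhaseSample:
    """Per-trial channel phases and the cross-channel PLV."""

    phases: np.ndarray  # (trials, channels), radians in (-pi, pi]
    plv: np.ndarray     # (trials,)
    probe_ms: float
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any(self.plv < 0) or np.any(self.plv > 1 + 1e-12):
            raise ValueError("PLV must lie in [0, 1]")


def plv(phases: np.ndarray) -> np.ndarray:
    """Resultant-vector length across the last axis, in [0, 1]."""
    return np.abs(np.exp(1j * np.asarray(phases)).mean(axis=-1))


def theta_phase_at(
    epochs: np.ndarray,
    fs: float,
    epoch_t0_ms: float,
    trial_meta: pd.DataFrame,
    probe_ms: float = DEFAULT_PROBE_MS,
    freq_hz: float = THETA_HZ,
) -> PhaseSample:
    """Channel-wise theta phase at the probe time, and per-trial PLV.

    ``epochs`` is (trials, channels, samples) starting at ``epoch_t0_ms``;
    the probe must sit far enough inside the epoch that the truncated theta
    kernel is fully supported.
    """
    k = morlet_kernel(freq_hz, fs)
    half = len(k) // 2
    idx = int(round((probe_ms - epoch_t0_ms) * fs / 1000.0))
    if idx - half < 0 or idx + half >= epochs.shape[-1]:
        raise ValueError("probe time outside epoch (kernel support clipped)")
    # complex wavelet coefficient at the probe sample only; for the
    # symmetric-envelope Morlet kernel, convolution at the probe equals the
    # inner product with the conjugate kernel centered there
    seg = epochs[:, :, idx - half: idx + half + 1]
    coeff = (seg * np.conj(k)[None, None, :]).sum(axis=-1)
    phases = np.angle(coeff)
    return PhaseSample(phases=phases, plv=plv(phases), probe_ms=probe_ms,
                       trial_meta=trial_meta.reset_index(drop=True))


def dunn_posthoc(groups: dict, bonferroni_by: int | None = None) -> dict:
    """Dunn's pairwise rank-sum post-hoc test with Bonferroni correction.

    Standard tie-corrected z statistic on mean ranks of the pooled sample.
    Returns {(label_a, label_b): corrected p}.
    """
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {}
    start = 0
    for g in labels:
        mean_rank[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    comparisons = list(combinations(labels, 2))
    m = bonferroni_by or len(comparisons)
    out = {}
    for a, b in comparisons:
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = float(min(p * m, 1.0))
    return out


def plv_category_tests(sample: PhaseSample, level: str) -> dict:
    """Rank-based comparison of PLV distributions across category members.

    Two groups: Mann-Whitney U.  Three or more: Kruskal-Wallis, followed by
    Dunn's pairwise post-hoc with Bonferroni correction.  Reports group
    medians.  Raises with a single group or an empty group.
    """
    labels = sample.trial_meta[level].to_numpy()
    valid = labels != "n/a"
    labels, vals = labels[valid], sample.plv[valid]
    groups = {g: vals[labels == g] for g in np.unique(labels)}
    if len(groups) < 2:
        raise ValueError(f"level {level!r} has a single group; nothing to test")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs >= 2 trials")
    report: dict = {
        "level": level,
        "medians": {g: float(np.median(v)) for g, v in groups.items()},
        "n": {g: int(len(v)) for g, v in groups.items()},
    }
    if len(groups) == 2:
        (ga, gb) = groups.values()
        u, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
        report.update(test="mannwhitney", statistic=float(u), p=float(p))
    else:
        h, p = stats.kruskal(*groups.values())
        report.update(test="kruskal", statistic=float(h), p=float(p),
                      pairwise=dunn_posthoc(groups))
    return report
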