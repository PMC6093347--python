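"""Ground-truth category tuning maps for the simulator.

Each cortical source on a fine lattice carries a multiplicative log-gain for
every category label, drawn from a Gaussian random field over source
positions.  Coarse-category fields use a long spatial correlation length and
are shared between the evoked-theta and induced-gamma signal components
(coarse clusters are stable across the response);  subordinate fields
(species, view, identity) use a short correlation length and are drawn
independently per component, so early-theta and late-gamma subordinate maps
decorrelate, as the analysis downstream is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform

from .config import SimConfig
from .stimuli import NA, StimulusSet, Stimulus

BANDS = ("theta", "gamma")
_FINE_LEVELS = ("species", "view", "identity")


def _source_lattice(config: SimConfig) -> np.ndarray:
    """Fine lattice of source positions covering the grid plus a margin."""
    width = (config.grid_cols - 1) * config.pitch_mm
    height = (config.grid_rows - 1) * config.pitch_mm
    margin = config.pitch_mm
    w, h = width + 2 * margin, height + 2 * margin
    # pick lattice shape with approximately n_sources points and square cells
    ny = max(2, int(round(np.sqrt(config.n_sources * h / w))))
    nx = max(2, int(round(config.n_sources / ny)))
    xs = np.linspace(-margin, width + margin, nx)
    ys = np.linspace(-margin, height + margin, ny)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _gp_cholesky(positions: np.ndarray, length_mm: float) -> np.ndarray:
    d2 = squareform(pdist(positions)) ** 2
    cov = np.exp(-d2 / (2.0 * length_mm**2))
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


@dataclass
class TuningMaps:
    """Per-source log-gain fields keyed by (component band, level, label)."""

    positions: np.ndarray  # (n_sources, 2) mm
    gains: dict  # (band, level, label) -> (n_sources,) log-gain field
    cluster_length_coarse_mm: float
    cluster_length_fine_mm: float
    _amp_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def log_gain(self, band: str, stimulus: Stimulus) -> np.ndarray:
        """Total log-gain at every source for one stimulus and component."""
        total = self.gains[(band, "coarse", stimulus.coarse)].copy()
        for level in _FINE_LEVELS:
            lab = stimulus.label(level)
            if lab != NA:
                total += self.gains[(band, level, lab)]
        return total

    def source_amplitude(self, band: str, stimulus: Stimulus) -> np.ndarray:
        """Multiplicative amplitude (exp of log-gain); cached per stimulus."""
        key = (band, stimulus.stimulus_id)
        if key not in self._amp_cache:
            self._amp_cache[key] = np.exp(self.log_gain(band, stimulus))
        return self._amp_cache[key]


def generate_tuning_maps(config: SimConfig, stimuli: StimulusSet) -> TuningMaps:
    """Draw the ground-truth tuning fields for a simulated session.

    Reproducible: the fields are fully determined by ``config`` (including
    ``config.seed``).  Raises if a correlation length is non-positive.
    """
    if config.cluster_length_coarse_mm <= 0 or config.cluster_length_fine_mm <= 0:
        raise ValueError("correlation lengths must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    positions = _source_lattice(config)
    chol_coarse = _gp_cholesky(positions, config.cluster_length_coarse_mm)
    chol_fine = _gp_cholesky(positions, config.cluster_length_fine_mm)
    n = positions.shape[0]

    gains: dict = {}
    for label in stimuli.labels("coarse"):
        f = config.gain_sd_coarse * (chol_coarse @ rng.standard_normal(n))
        for band in BANDS:  # coarse tuning shared across components
            gains[(band, "coarse", label)] = f
    for band in BANDS:
        for level in _FINE_LEVELS:
            for label in stimuli.labels(level):
                gains[(band, level, label)] = config.gain_sd_fine * (
                    chol_fine @ rng.standard_normal(n)
                )
    return TuningMaps(
        positions=positions,
        gains=gains,
        cluster_length_coarse_mm=config.cluster_length_coarse_mm,
        cluster_length_fine_mm=config.cluster_length_fine_mm,
    )


def spatial_autocorr_length(
    positions: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
) -> float:
    """Empirical spatial autocorrelation length of a field.

    Bins pairwise products of the standardized field by distance and fits
    ``corr(d) = exp(-d / L)`` by least squares; returns the fitted ``L`` (mm).
    """
    z = np.asarray(values, dtype=float)
    z = (z - z.mean()) / z.std()
    d = pdist(positions)
    iu = np.triu_indices(len(z), k=1)
    prod = z[iu[0]] * z[iu[1]]
    edges = np.linspace(0, np.quantile(d, 0.7), n_bins + 1)
    centers, corrs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d >= lo) & (d < hi)
        if m.sum() >= 10:
            centers.append(0.5 * (lo + hi))
            corrs.append(prod[m].mean())
    centers = np.asarray(centers)
    corrs = np.asarray(corrs)
    (length,), _ = curve_fit(
        lambda x, L: np.exp(-x / L), centers, corrs,
        p0=[max(centers.mean(), 1e-3)], bounds=(1e-6, 1e3), maxfev=10000,
    )
    return float(length)
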