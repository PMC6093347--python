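"""Simulation configuration.

Defaults emulate the recording geometry and task timing of a chronic
inferotemporal implant: a 60-channel penetrating-microelectrode grid at
1.2-mm pitch with a companion surface grid offset by half a pitch, 300-ms
stimulus presentations separated by 600-900-ms blanks, and category tuning
fields whose spatial correlation length is long for coarse categories and
short for subordinate (species/view/identity) categories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class SimConfig:
    # geometry
    grid_rows: int = 6
    grid_cols: int = 10
    pitch_mm: float = 1.2
    # acquisition
    sample_rate_hz: float = 1000.0
    # trial schedule
    n_trials_per_stimulus: int = 8
    stim_duration_ms: float = 300.0
    iti_ms_range: tuple[float, float] = (600.0, 900.0)
    # sensor spatial-summation radii (Gaussian pickup sigma, mm)
    r_mua_mm: float = 0.25
    r_lfp_mm: float = 0.6
    r_ecog_mm: float = 2.5
    # tuning-field correlation lengths (mm)
    cluster_length_coarse_mm: float = 6.0
    cluster_length_fine_mm: float = 0.6
    # effect sizes
    evoked_theta_amp: float = 1.3
    induced_gamma_amp: float = 1.0
    gain_sd_coarse: float = 0.45
    gain_sd_fine: float = 0.45
    phase_jitter_by_category: dict = field(
        default_factory=lambda: {"default": 0.15, "right": 0.7}
    )
    # noise
    shared_noise_sd: float = 0.6
    private_noise_sd: float = 1.5
    #: trial-to-trial log-normal variability of each source's response gain;
    #: spatial summation averages this away, local pickup does not
    source_noise_sd: float = 0.4
    # spiking
    base_rate_hz: float = 5.0
    spike_gain_hz: float = 8.0
    # source lattice
    n_sources: int = 300
    # stimulus-set exemplar counts (human faces are the fixed 3 x 5 block)
    n_monkey_faces: int = 6
    n_bodies: int = 6
    n_objects: int = 6
    n_modified_faces: int = 3
    n_body_parts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.iti_ms_range = tuple(self.iti_ms_range)  # type: ignore[assignment]
        positive = [
            ("grid_rows", self.grid_rows), ("grid_cols", self.grid_cols),
            ("pitch_mm", self.pitch_mm), ("sample_rate_hz", self.sample_rate_hz),
            ("n_trials_per_stimulus", self.n_trials_per_stimulus),
            ("stim_duration_ms", self.stim_duration_ms),
            ("r_mua_mm", self.r_mua_mm), ("r_lfp_mm", self.r_lfp_mm),
            ("r_ecog_mm", self.r_ecog_mm),
            ("cluster_length_coarse_mm", self.cluster_length_coarse_mm),
            ("cluster_length_fine_mm", self.cluster_length_fine_mm),
            ("n_sources", self.n_sources),
        ]
        for name, value in positive:
            if value <= 0:
                raise ValueError(f"{name} must be > 0 (got {value})")
        lo, hi = self.iti_ms_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid iti_ms_range {self.iti_ms_range}")
        if self.r_ecog_mm <= self.r_lfp_mm:
            raise ValueError("r_ecog_mm must exceed r_lfp_mm")
        if self.cluster_length_coarse_mm <= self.cluster_length_fine_mm:
            raise ValueError(
                "cluster_length_coarse_mm must exceed cluster_length_fine_mm"
            )

    @property
    def n_channels(self) -> int:
        return self.grid_rows * self.grid_cols

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
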