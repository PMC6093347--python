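"""End-to-end pipeline driver with manifest-based reproducibility.

A :class:`PipelineConfig` validates the run description (unknown keys are
rejected); :func:`run_pipeline` sequences simulate -> features -> decode ->
shuffle -> maps -> report, derives every stage's random seed from one master
seed, hashes every artifact into a :class:`RunManifest`, and aborts with a
stage-tagged error if any stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .decoding import DecodeSpec, level_accuracy, level_pairs, pairwise_decode
from .extract import (band_response_from_session, spike_rate_features,
                      theta_phase_from_session, total_power_from_session)
from .io import write_session
from .maps import EARLY_WINDOW_MS, LATE_WINDOW_MS, dprime_map
from .phase import plv_category_tests
from .shuffle import compare_conditions, decode_with_trial_shuffle, shuffle_curve
from .simulate import simulate_session
from .stimuli import make_stimulus_set
from .tuning import generate_tuning_maps

log = logging.getLogger("itcdecode")

_ALLOWED_LEVELS = ("coarse", "species", "view", "identity")
_ALLOWED_MODALITIES = ("lfp", "ecog", "mua")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    modalities: tuple[str, ...] = ("lfp", "ecog", "mua")
    levels: tuple[str, ...] = ("coarse", "species")
    n_selected_features: int = 100
    shuffle_sizes: tuple[int, ...] = (4, 10, 30, 60)
    run_shuffles: bool = True
    run_maps: bool = True
    seed: int = 0
    out_dir: str = "itcdecode_run"

    def __post_init__(self) -> None:
        for m in self.modalities:
            if m not in _ALLOWED_MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        for lv in self.levels:
            if lv not in _ALLOWED_LEVELS:
                raise ValueError(f"unknown level {lv!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(data["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            data["sim"] = SimConfig(**data["sim"])
        for key in ("modalities", "levels", "shuffle_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_hashes: dict
    timestamps: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    from . import __version__

    os.makedirs(config.out_dir, exist_ok=True)
    stage_hashes: dict = {}
    timestamps: dict = {}

    def _record(stage: str, path: str) -> None:
        stage_hashes.setdefault(stage, {})[os.path.basename(path)] = \
            _file_hash(path)
        timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def _write_json(stage: str, name: str, payload) -> None:
        path = os.path.join(config.out_dir, name)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        _record(stage, path)

    try:
        stage = "simulate"
        log.info("[%s] starting", stage)
        sim_cfg = config.sim.replace(seed=_stage_seed(config.seed, "simulate"))
        stimuli = make_stimulus_set(sim_cfg)
        maps = generate_tuning_maps(sim_cfg, stimuli)
        session = simulate_session(sim_cfg, stimuli, maps)
        session_path = os.path.join(config.out_dir, "session.h5")
        write_session(session, session_path)
        _record(stage, session_path)

        stage = "features"
        log.info("[%s] starting", stage)
        tables = {}
        for modality in config.modalities:
            if modality == "mua":
                tables[modality] = spike_rate_features(session, stimuli)
            else:
                tables[modality] = total_power_from_session(
                    session, stimuli, modality)
            prefix = os.path.join(config.out_dir, f"features_{modality}")
            tables[modality].to_files(prefix)
            _record(stage, prefix + ".csv")

        stage = "decode"
        log.info("[%s] starting", stage)
        decode_seed = _stage_seed(config.seed, "decode")
        decode_report: dict = {}
        for modality in config.modalities:
            decode_report[modality] = {}
            for level in config.levels:
                results = {}
                for pair in level_pairs(level):
                    spec = DecodeSpec(level, pair,
                                      config.n_selected_features,
                                      seed=decode_seed)
                    r = pairwise_decode(spec, tables[modality])
                    results[pair] = r
                    decode_report[modality].setdefault(level, {})[
                        "-vs-".join(pair)] = {
                        "accuracy_pct": r.accuracy_pct,
                        "ci95_pct": list(r.ci95_pct),
                        "folds": [[f.n_test, f.n_correct] for f in r.folds],
                    }
                decode_report[modality][level]["pooled_pct"] = \
                    level_accuracy(level, results)
        _write_json(stage, "decode.json", decode_report)

        shuffle_report: dict = {}
        if config.run_shuffles:
            stage = "shuffle"
            log.info("[%s] starting", stage)
            shuffle_seed = _stage_seed(config.seed, "shuffle")
            spec = DecodeSpec("coarse", ("face", "body"),
                              config.n_selected_features, seed=decode_seed)
            sizes = [s for s in config.shuffle_sizes
                     if s <= config.sim.n_channels]
            curve = shuffle_curve(spec, tables["lfp"],
                                  config.sim.grid_rows, config.sim.grid_cols,
                                  sizes=sizes, seed=shuffle_seed)
            conditions = {
                "original": pairwise_decode(spec, tables["lfp"]),
                "shuffle-train": decode_with_trial_shuffle(
                    spec, tables["lfp"], "train-only", seed=shuffle_seed),
                "shuffle-train+test": decode_with_trial_shuffle(
                    spec, tables["lfp"], "train+test", seed=shuffle_seed),
            }
            shuffle_report = {
                "spatial": {
                    "sizes": curve.sizes.tolist(),
                    "accuracies_pct": curve.accuracies_pct.tolist(),
                    "fit": {"A": curve.fit.A, "B": curve.fit.B,
                            "C": curve.fit.C, "no_decay": curve.fit.no_decay},
                    "max_drop_pct": curve.max_drop_pct,
                },
                "trial": {
                    "accuracy_pct": {k: v.accuracy_pct
                                     for k, v in conditions.items()},
                    "comparisons": [
                        {"pair": list(c.pair), "p_bonferroni": c.p_bonferroni}
                        for c in compare_conditions(conditions)
                    ],
                },
            }
            _write_json(stage, "shuffle.json", shuffle_report)

        maps_report: dict = {}
        if config.run_maps:
            stage = "maps"
            log.info("[%s] starting", stage)
            for band, window, tag in (("theta4", EARLY_WINDOW_MS, "theta-early"),
                                      ("highgamma80", LATE_WINDOW_MS,
                                       "highgamma-late")):
                resp = band_response_from_session(
                    session, stimuli, "lfp", band, response_window_ms=window)
                smap = dprime_map(resp, "species", tag,
                                  geometry=session.geometry_lfp)
                path = os.path.join(config.out_dir, f"map_species_{tag}.csv")
                smap.table.to_csv(path, index=False)
                _record(stage, path)
                maps_report[tag] = {
                    "n_selective": int((np.abs(smap.dprime) > 1).sum()),
                }
            phases = theta_phase_from_session(session, stimuli, "lfp")
            try:
                plv_report = plv_category_tests(phases, "view")
                if "pairwise" in plv_report:
                    plv_report["pairwise"] = {
                        "-vs-".join(k): v
                        for k, v in plv_report["pairwise"].items()}
                maps_report["plv_view"] = plv_report
            except ValueError:
                pass
            _write_json(stage, "maps.json", maps_report)

        stage = "report"
        summary = {"decode": decode_report, "shuffle": bool(shuffle_report),
                   "maps": bool(maps_report)}
        _write_json(stage, "report.json", summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True,
                       default=str).encode()).hexdigest(),
        seed=config.seed,
        version=__version__,
        stage_hashes=stage_hashes,
        timestamps=timestamps,
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def verify_manifest(manifest: RunManifest, out_dir: str) -> list[str]:
    """Return the artifacts whose on-disk hash no longer matches."""
    bad = []
    for stage, files in manifest.stage_hashes.items():
        for name, digest in files.items():
            path = os.path.join(out_dir, name)
            if not os.path.exists(path) or _file_hash(path) != digest:
                bad.append(f"{stage}:{name}")
    return bad
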