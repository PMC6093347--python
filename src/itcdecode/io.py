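"""Session container I/O (HDF5).

Layout: groups ``/lfp`` and ``/ecog`` (channels x samples float32),
``/spikes/chNN`` (float64 seconds), ``/trials`` (onset_sample, stimulus_id),
``/geometry/{lfp,ecog}``, root attributes ``config`` (JSON), ``seed`` and
``sample_rate_hz``.  Round trips are lossless.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .simulate import Session

_REQUIRED = ("lfp", "ecog", "spikes", "trials", "geometry")


class SchemaError(ValueError):
    pass


def write_session(session: Session, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        f.create_dataset("ecog", data=session.ecog.astype(np.float32))
        g = f.create_group("spikes")
        for ch, times in enumerate(session.spikes):
            g.create_dataset(f"ch{ch:02d}", data=np.asarray(times, np.float64))
        t = f.create_group("trials")
        t.create_dataset("onset_sample",
                         data=session.trials["onset_sample"].to_numpy(np.int64))
        sid = session.trials["stimulus_id"].to_numpy()
        t.create_dataset("stimulus_id",
                         data=np.array(sid, dtype=h5py.string_dtype()))
        geo = f.create_group("geometry")
        geo.create_dataset("lfp", data=session.geometry_lfp)
        geo.create_dataset("ecog", data=session.geometry_ecog)
        f.attrs["sample_rate_hz"] = session.sample_rate_hz
        f.attrs["config"] = session.config_json
        f.attrs["seed"] = session.seed


def read_session(path: str) -> Session:
    with h5py.File(path, "r") as f:
        for group in _REQUIRED:
            if group not in f:
                raise SchemaError(f"missing group /{group}")
        for sub in ("onset_sample", "stimulus_id"):
            if sub not in f["trials"]:
                raise SchemaError(f"missing dataset /trials/{sub}")
        lfp = f["lfp"][...]
        ecog = f["ecog"][...]
        if lfp.ndim != 2 or ecog.shape != lfp.shape:
            raise SchemaError("/lfp and /ecog must be matching 2-D arrays")
        n_ch = lfp.shape[0]
        spikes = []
        for ch in range(n_ch):
            key = f"ch{ch:02d}"
            if key not in f["spikes"]:
                raise SchemaError(f"missing dataset /spikes/{key}")
            times = f["spikes"][key][...]
            if times.ndim != 1 or np.any(np.diff(times) <= 0):
                raise SchemaError(f"corrupt spike array /spikes/{key}")
            spikes.append(times)
        onset = f["trials"]["onset_sample"][...]
        sid = [s.decode() if isinstance(s, bytes) else s
               for s in f["trials"]["stimulus_id"][...]]
        trials = pd.DataFrame({"onset_sample": onset.astype(np.int64),
                               "stimulus_id": sid})
        session = Session(
            lfp=lfp, ecog=ecog, spikes=spikes, trials=trials,
            geometry_lfp=f["geometry"]["lfp"][...],
            geometry_ecog=f["geometry"]["ecog"][...],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            config_json=str(f.attrs.get("config", "")),
            seed=int(f.attrs.get("seed", 0)),
        )
    session.validate()
    return session
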