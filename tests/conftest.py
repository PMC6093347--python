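import numpy as np
import pytest

from itcdecode import (SimConfig, generate_tuning_maps, make_stimulus_set,
                       simulate_session)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """Reduced-scale study conditions used throughout the unit tests."""
    base = dict(
        n_trials_per_stimulus=4,
        n_monkey_faces=4, n_bodies=4, n_objects=4,
        n_modified_faces=2, n_body_parts=2,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_bundle():
    """One small simulated session shared by read-only tests."""
    cfg = small_config()
    stim = make_stimulus_set(cfg)
    maps = generate_tuning_maps(cfg, stim)
    session = simulate_session(cfg, stim, maps)
    return cfg, stim, maps, session


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
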