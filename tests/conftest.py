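import numpy as np
import pytest
from hypothesis import settings

import imbfall

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from imbfall import model as M
from imbfall.pipeline import RunConfig, prepare_split


def make_trial(smv_values, fs=200.0, activity="standing", trial_id="t"):
    """Trial whose SMV trace equals the given values (all signal on z)."""
    vals = np.asarray(smv_values, dtype=float)
    samples = np.zeros((vals.size, 3))
    samples[:, 2] = vals
    return imbfall.SensorTrial(
        samples=samples, fs=fs, activity_class=activity, trial_id=trial_id
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Fast low-rate corpus for pipeline-level tests: 60 ADL / 18 fall trials
    at 50 Hz -> a few hundred 1 s windows, imbalanced about 7:1."""
    sim = imbfall.SimulationConfig(
        n_adl=60, n_fall=18, fs=50.0, adl_duration_s=6.0, fall_duration_s=8.0, master_seed=7
    )
    cfg = RunConfig(
        simulation=sim,
        split_seed=7,
        network=M.NetworkConfig(
            channels=(8, 16), input_shape=(50, 3), max_epochs=4, batch_size=32, seed=7
        ),
    )
    split, manifest = prepare_split(cfg)
    return cfg, split, manifest
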