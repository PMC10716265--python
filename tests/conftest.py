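import numpy as np
import pytest

from afhorizon.pipeline import PipelineConfig, run_experiment
from afhorizon.simulate import SimProfile


@pytest.fixture(scope="session")
def quiet_profile():
    """Pure-sinus profile: no AF, ectopy or artifacts."""
    return SimProfile(af_episode_rate=0, pac_rate=0, pvc_rate=0,
                      artifact_rate=0)


@pytest.fixture(scope="session")
def reference_experiment():
    """The package's reference end-to-end study (shared across tests).

    600 train / 300 calibration / 300 test subjects at design prevalence
    20%, 12-h recordings, 1-h AF-free inputs scored as 10-min and 1-h
    scenarios, demographics-only versus all-features models.
    """
    cfg = PipelineConfig(feature_sets=("ag", "all_features"), n_boot=500)
    return run_experiment(cfg, seed=7)


def rng(seed=0):
    return np.random.default_rng(seed)
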