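import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pingmap import DesignConfig, EpochTiming, ForwardModel
from pingmap.simulate import generate_design, generate_epochs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_cfg() -> DesignConfig:
    return DesignConfig(seed=11)


@pytest.fixture(scope="session")
def small_timing() -> EpochTiming:
    return EpochTiming(tmin=-0.3, tmax=0.5, pad=0.2, cue_onset=0.0,
                       ping_onset=None)


@pytest.fixture(scope="session")
def localizer_trials(design_cfg):
    trials = generate_design(design_cfg, n_trials_train=120, n_trials_test=8)
    return trials[trials["phase"] == "training"]


@pytest.fixture(scope="session")
def _noisy_epochs_master(localizer_trials, small_timing):
    fwd = ForwardModel()
    return generate_epochs(localizer_trials, fwd, small_timing, seed=21,
                           hpl_bin=4)


@pytest.fixture
def noisy_epochs(_noisy_epochs_master):
    """Per-test copy so mutation cannot leak across tests."""
    return _noisy_epochs_master.copy()


@pytest.fixture(scope="session")
def noiseless_epochs(localizer_trials, small_timing):
    fwd = ForwardModel(noise_pink=0.0, noise_white=0.0, induced_amp=0.0)
    return generate_epochs(localizer_trials, fwd, small_timing, seed=22,
                           hpl_bin=4)
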