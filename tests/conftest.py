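import pytest

import cspine as cs


@pytest.fixture(scope="session")
def model() -> cs.SpineModel:
    return cs.SpineModel.default()


@pytest.fixture(scope="session")
def phys_capture(model):
    """Noise-free physiological capture; 401 frames puts the end-range
    instants exactly on the sampling grid."""
    sc = cs.ScenarioConfig.physiological(noise_sigma=0.0, n_frames=401, seed=11)
    return cs.generate_trajectory(model, sc)


@pytest.fixture(scope="session")
def inst_capture(model):
    sc = cs.ScenarioConfig.instability(noise_sigma=0.0, n_frames=401, seed=12)
    return cs.generate_trajectory(model, sc)
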