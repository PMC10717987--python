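import numpy as np
import pytest

from gaitkin import kinematic_model as km
from gaitkin import marker_protocol as mp
from gaitkin import synthetic_data as sd
from gaitkin.calibration import calibrate


@pytest.fixture(scope="session")
def nominal_model():
    return km.build_model()


@pytest.fixture(scope="session")
def plugin(nominal_model):
    return mp.plugin_marker_set(nominal_model)


@pytest.fixture(scope="session")
def redundant(nominal_model):
    return mp.redundant_marker_set(nominal_model)


@pytest.fixture(scope="session")
def truth_model():
    """A subject whose lengths differ from nominal on every parameter."""
    return km.build_model({"pelvic_width": 252.0, "thigh_L": 395.0, "thigh_R": 420.0,
                           "shank_L": 385.0, "shank_R": 405.0,
                           "foot_L": 242.0, "foot_R": 260.0})


@pytest.fixture(scope="session")
def calibrated(truth_model):
    """Noiseless Redundant-protocol calibration of the truth subject."""
    proto = mp.redundant_marker_set(truth_model)
    standing = sd.generate_standing(truth_model, proto, sd.NoiseConfig(seed=11))
    return calibrate(standing, proto)


@pytest.fixture(scope="session")
def short_trial(truth_model):
    """A noiseless 2-stride walking trial of the truth subject."""
    proto = mp.redundant_marker_set(truth_model)
    return sd.generate_trial(truth_model, proto,
                             sd.GaitTrajectoryConfig(n_strides=2),
                             sd.NoiseConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
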