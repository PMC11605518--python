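import numpy as np
import pytest

from emgagg.data import FeatureMatrix, KinematicTrace
from emgagg.synthgen import (
    DriftModel,
    MovementProtocol,
    MovementSpec,
    default_protocol,
    default_subject,
    make_kinematic_trace,
    synthesize_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_protocol():
    """Two single-DOF movements, three trials each (fast unit-test scale)."""
    return default_protocol(n_movements=2, trials_per_movement=3)


@pytest.fixture
def subject():
    return default_subject(n_contacts=4, seed=11)


@pytest.fixture
def zero_drift():
    return DriftModel(rotation_rate=0.0, gain_sd_per_day=0.0, baseline_sd_per_day=0.0, seed=3)


@pytest.fixture
def feature_session(small_protocol, subject):
    """Feature-level session: (features, displayed kinematics, annotations)."""
    kin, annotations = make_kinematic_trace(small_protocol)
    feats = synthesize_features(kin, subject, seed=7)
    return feats, kin, annotations
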