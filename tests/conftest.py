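from dataclasses import replace

import numpy as np
import pytest

from oiload.limb_model import (
    AmputationConfig,
    SubjectAnthropometry,
    apply_virtual_amputation,
    attach_prosthesis,
    build_intact_model,
    prosthesis_preset,
)
from oiload.motion_synth import MotionTrial


@pytest.fixture
def subject() -> SubjectAnthropometry:
    return SubjectAnthropometry(body_mass=70.0, stature=1.75,
                                upper_arm_length=0.3255, elbow_width=0.070,
                                wrist_width=0.0525, hand_length=0.189)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def zero_radius(model):
    """Zero every transverse radius (rod inertia), for exactness properties."""
    return replace(model, segments=tuple(
        replace(s, transverse_radius=0.0) for s in model.segments))


def prosthetic_model(subject, category="advanced", level=0.25, **cfg_kwargs):
    cfg = AmputationConfig(level=level, **cfg_kwargs)
    return attach_prosthesis(
        apply_virtual_amputation(build_intact_model(subject), cfg),
        prosthesis_preset(category), cfg)


def static_trial(n=50, sample_rate=100.0, quat=(1.0, 0.0, 0.0, 0.0),
                 elbow_flexion=0.0, activity="jumping_jack",
                 handheld_mass=0.0) -> MotionTrial:
    t = np.arange(n) / sample_rate
    return MotionTrial(activity=activity, sample_rate=sample_rate, time=t,
                       shoulder_position=np.zeros((n, 3)),
                       quaternions=np.tile(np.asarray(quat, float), (n, 1)),
                       elbow_flexion=elbow_flexion,
                       handheld_mass=handheld_mass)
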