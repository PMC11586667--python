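"""Shared fixtures: synthetic sessions analyzed once per test run."""

import numpy as np
import pytest

from therapose.io_streams import COCO_JOINTS, RunConfig
from therapose.pipeline import analyze_session
from therapose.skeleton_features import SkeletonFrame
from therapose.synth_session import KEYBOARD_SPAN, generate, published_profile_script


def make_config(**overrides) -> RunConfig:
    cfg = RunConfig(keyboard_span=KEYBOARD_SPAN)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def seated_frame(frame_index=0, **joint_overrides) -> SkeletonFrame:
    """A plausible seated skeleton (shoulder width 100 px) for unit tests."""
    joints = {
        "nose": (345.0, 150.0),
        "left_eye": (315.0, 143.0),
        "right_eye": (335.0, 143.0),
        "left_ear": (300.0, 150.0),
        "right_ear": (340.0, 150.0),
        "left_shoulder": (270.0, 200.0),
        "right_shoulder": (370.0, 200.0),
        "left_elbow": (250.0, 270.0),
        "right_elbow": (390.0, 270.0),
        "left_wrist": (230.0, 330.0),
        "right_wrist": (410.0, 330.0),
        "left_hip": (285.0, 350.0),
        "right_hip": (355.0, 350.0),
        "left_knee": (300.0, 450.0),
        "right_knee": (340.0, 450.0),
        "left_ankle": (300.0, 550.0),
        "right_ankle": (340.0, 550.0),
    }
    joints.update(joint_overrides)
    xy = np.array([joints[name] for name in COCO_JOINTS], dtype=float)
    return SkeletonFrame(
        frame_index, int(frame_index * 20), xy, np.full(len(COCO_JOINTS), 0.9)
    )


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory):
    """A 2-minute noiseless scripted session, generated and fully analyzed."""
    script = published_profile_script(
        "subjectA_first", duration_min=2.0, noise=0.0, spike_rate=0.0, seed=3
    )
    out = tmp_path_factory.mktemp("zero_noise")
    session = generate(script, out)
    states, summary = analyze_session(
        session.paths["keypoints"],
        session.paths["events"],
        audio_path=session.paths["audio"],
        config=make_config(),
    )
    return script, session, states, summary


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """A 5-minute session at default jitter/spike levels, fully analyzed."""
    script = published_profile_script("subjectB_last", duration_min=5.0, seed=0)
    out = tmp_path_factory.mktemp("noisy")
    session = generate(script, out)
    states, summary = analyze_session(
        session.paths["keypoints"],
        session.paths["events"],
        audio_path=session.paths["audio"],
        config=make_config(),
    )
    return script, session, states, summary
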