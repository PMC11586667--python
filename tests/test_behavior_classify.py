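"""Per-frame classifiers, label smoothing, and cross-attribute invariants."""

import numpy as np
import pytest

from conftest import make_config, seated_frame
from therapose.behavior_classify import (
    ClassifierThresholds,
    classify_body_pose,
    classify_head_pose,
    classify_playing_hand,
    classify_self_touch,
    classify_torso_pose,
    smooth_labels,
    smooth_states,
)
from therapose.errors import ConfigurationError
from therapose.skeleton_features import distance_matrix, geometric_features
from therapose.synth_session import KEYBOARD_SPAN

TH = ClassifierThresholds()


def _features(**overrides):
    return geometric_features(seated_frame(**overrides))


class TestBodyPose:
    def test_at_baseline_is_sitting(self):
        feat = _features()
        assert classify_body_pose(feat, 350.0, 150.0, TH) == "sitting"

    def test_risen_beyond_half_torso_is_standing(self):
        frame = seated_frame(
            left_hip=(285.0, 260.0), right_hip=(355.0, 260.0)  # risen 90 = 0.6 torso
        )
        feat = geometric_features(frame)
        assert classify_body_pose(feat, 350.0, 150.0, TH) == "standing"

    def test_small_rise_stays_sitting(self):
        frame = seated_frame(left_hip=(285.0, 290.0), right_hip=(355.0, 290.0))
        feat = geometric_features(frame)  # risen 60 = 0.4 torso
        assert classify_body_pose(feat, 350.0, 150.0, TH) == "sitting"


class TestSelfTouch:
    def test_wrists_at_rest_touch_nothing(self):
        frame = seated_frame()
        region, wp = classify_self_touch(frame, distance_matrix(frame), False, TH)
        assert (region, wp) == ("none", False)

    def test_wrist_at_nose_is_head_region(self):
        frame = seated_frame(right_wrist=(345.0, 150.0))
        region, wp = classify_self_touch(frame, distance_matrix(frame), False, TH)
        assert (region, wp) == ("head_upper_torso", False)

    def test_touch_during_note_flagged_while_playing(self):
        frame = seated_frame(right_wrist=(345.0, 150.0))
        region, wp = classify_self_touch(frame, distance_matrix(frame), True, TH)
        assert (region, wp) == ("head_upper_torso", True)

    def test_wrist_at_hip_is_middle_region(self):
        frame = seated_frame(left_wrist=(285.0, 345.0))
        region, _ = classify_self_touch(frame, distance_matrix(frame), False, TH)
        assert region == "middle_torso"

    def test_touch_time_monotone_in_radius(self):
        rng = np.random.default_rng(31)
        frames = []
        for _ in range(100):
            frame = seated_frame(
                right_wrist=tuple(rng.uniform([250, 100], [420, 400]))
            )
            frames.append((frame, distance_matrix(frame)))
        counts = []
        for radius in (0.2, 0.5, 0.9):
            th = ClassifierThresholds(touch_radius_ratio=radius)
            counts.append(
                sum(
                    classify_self_touch(f, d, False, th)[0] != "none"
                    for f, d in frames
                )
            )
        assert counts == sorted(counts)


class TestPlayingHand:
    def test_not_playing_forced(self):
        assert classify_playing_hand(seated_frame(), False, KEYBOARD_SPAN) == "not_playing"

    def test_both_wrists_in_span(self):
        frame = seated_frame(left_wrist=(270.0, 420.0), right_wrist=(370.0, 420.0))
        assert classify_playing_hand(frame, True, KEYBOARD_SPAN) == "both"

    def test_single_wrist_in_span(self):
        frame = seated_frame(right_wrist=(370.0, 420.0))
        assert classify_playing_hand(frame, True, KEYBOARD_SPAN) == "right"

    def test_fallback_to_nearest_wrist(self):
        frame = seated_frame(
            left_wrist=(230.0, 330.0), right_wrist=(370.0, 390.0)  # none inside
        )
        assert classify_playing_hand(frame, True, KEYBOARD_SPAN) == "right"

    def test_occlusion_votes_when_wrists_fail(self):
        frame = seated_frame()  # both wrists at rest, outside the span
        got = classify_playing_hand(frame, True, KEYBOARD_SPAN, occlusion=(True, False))
        assert got == "left"

    def test_missing_span_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            classify_playing_hand(seated_frame(), True, None)


class TestHeadAndTorso:
    @pytest.mark.parametrize(
        "nose,expect",
        [
            ((345.0, 150.0), "neutral"),  # level with the ear line: tilt 0
            ((345.0, 125.0), "up"),  # +45 deg, over the +15 cutoff
            ((345.0, 175.0), "down"),  # -45 deg, under the -15 cutoff
        ],
    )
    def test_head_pose_band(self, nose, expect):
        frame = seated_frame(nose=nose)
        assert classify_head_pose(geometric_features(frame), TH) == expect

    def test_head_pose_threshold_crossing(self):
        just_over = _features(nose=(335.0, 145.0))  # dy 5, dx 15 -> 18.4 deg
        assert classify_head_pose(just_over, TH) == "up"
        just_under = _features(nose=(335.0, 147.0))  # dy 3, dx 15 -> 11.3 deg
        assert classify_head_pose(just_under, TH) == "neutral"

    def test_torso_neutral_unless_both_hands(self):
        wide = _features(left_elbow=(220.0, 270.0), right_elbow=(420.0, 270.0))
        assert classify_torso_pose(wide, "right", TH) == "neutral"
        assert classify_torso_pose(wide, "not_playing", TH) == "neutral"

    def test_torso_open_and_closed_ratios(self):
        open_feat = _features(left_elbow=(220.0, 270.0), right_elbow=(420.0, 270.0))
        assert open_feat.elbow_spread / open_feat.shoulder_width == pytest.approx(2.0)
        assert classify_torso_pose(open_feat, "both", TH) == "open"
        closed_feat = _features(left_elbow=(270.0, 270.0), right_elbow=(370.0, 270.0))
        assert classify_torso_pose(closed_feat, "both", TH) == "closed"


def _oracle_smooth(labels, smooth_ms, fps):
    """Reference run-length filter working directly on the flat label list."""
    labels = list(labels)
    while True:
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i, labels[start]))
                start = i
        if len(runs) <= 1:
            return labels
        shorts = [
            (e - s, s, k) for k, (s, e, _) in enumerate(runs) if (e - s) * 1000 < smooth_ms * fps
        ]
        if not shorts:
            return labels
        _, _, k = min(shorts)
        s, e, _ = runs[k]
        if k == 0:
            donor = runs[1]
        elif k == len(runs) - 1:
            donor = runs[k - 1]
        else:
            left, right = runs[k - 1], runs[k + 1]
            donor = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        labels[s:e] = [donor[2]] * (e - s)


class TestSmoothing:
    def test_constant_stream_unchanged(self):
        labels = ["a"] * 50
        assert smooth_labels(labels, 100, 50) == labels

    def test_single_frame_spike_removed(self):
        labels = ["neutral"] * 20 + ["up"] + ["neutral"] * 20
        assert smooth_labels(labels, 100, 50) == ["neutral"] * 41

    def test_run_of_exactly_smooth_ms_kept(self):
        labels = ["a"] * 20 + ["b"] * 5 + ["a"] * 20  # 5 frames = 100 ms at 50 fps
        assert smooth_labels(labels, 100, 50) == labels

    def test_matches_flat_list_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(200):
            n = int(rng.integers(1, 80))
            labels = [str(x) for x in rng.integers(0, 3, n)]
            smooth_ms = float(rng.choice([60, 100, 200]))
            assert smooth_labels(labels, smooth_ms, 50) == _oracle_smooth(
                labels, smooth_ms, 50
            )

    def test_invariants_hold_after_session_smoothing(self, noisy_run):
        _, _, states, _ = noisy_run
        for s in states:
            s.validate()  # raises on any cross-attribute violation

    def test_smooth_states_enforces_hand_playing_consistency(self, noisy_run):
        _, _, states, _ = noisy_run
        resmoothed = smooth_states(states, 100, 50)
        for s in resmoothed:
            assert (s.playing_hand == "not_playing") == (not s.playing)
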