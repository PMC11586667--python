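"""Outlier repair, distance matrices and geometric features."""

import numpy as np
import pytest

from conftest import seated_frame
from therapose.errors import CalibrationError, ValidationError
from therapose.io_streams import COCO_JOINTS, JOINT_INDEX
from therapose.skeleton_features import (
    SkeletonFrame,
    distance_matrix,
    geometric_features,
    median_shoulder_width,
    repair_outliers,
)


def _sequence(n=20, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n):
        base = seated_frame(f)
        xy = base.xy + rng.normal(0, jitter, base.xy.shape)
        frames.append(SkeletonFrame(f, f * 20, xy, base.score.copy()))
    return frames


class TestRepair:
    def test_clean_sequence_unchanged(self):
        frames = _sequence(10)
        repaired = repair_outliers(frames)
        for orig, rep in zip(frames, repaired):
            np.testing.assert_array_equal(orig.xy, rep.xy)
            assert rep.repaired == frozenset()

    def test_single_frame_spike_replaced_by_previous(self):
        frames = _sequence(10)
        nose = JOINT_INDEX["nose"]
        frames[5].xy[nose] += 1000.0  # 10x shoulder width
        repaired = repair_outliers(frames)
        np.testing.assert_array_equal(repaired[5].xy[nose], repaired[4].xy[nose])
        assert repaired[5].repaired == frozenset({"nose"})
        assert repaired[6].repaired == frozenset()

    def test_missing_person_frame_fully_copied(self):
        frames = _sequence(6)
        frames[3] = SkeletonFrame(3, 60, np.zeros((17, 2)), np.zeros(17))
        repaired = repair_outliers(frames)
        np.testing.assert_array_equal(repaired[3].xy, repaired[2].xy)
        assert repaired[3].repaired == frozenset(COCO_JOINTS)

    def test_matches_joint_by_joint_reapplication(self):
        """The vectorized path equals a scalar causal re-application of the rule."""
        rng = np.random.default_rng(42)
        frames = _sequence(60, jitter=2.0, seed=1)
        for _ in range(8):  # random spikes and score dropouts
            f = rng.integers(1, 60)
            j = rng.integers(0, 17)
            if rng.random() < 0.5:
                frames[f].xy[j] += rng.choice([-1, 1], 2) * 400.0
            else:
                frames[f].score[j] = 0.05

        msw = median_shoulder_width(frames)
        xy = np.array([f.xy for f in frames])
        score = np.array([f.score for f in frames])
        expect = xy.copy()
        expected_sets = [set()]
        for t in range(1, len(frames)):
            flagged = set()
            for j in range(17):
                disp = np.hypot(*(xy[t, j] - expect[t - 1, j]))
                if score[t, j] < 0.3 or disp > msw:
                    expect[t, j] = expect[t - 1, j]
                    flagged.add(COCO_JOINTS[j])
            expected_sets.append(flagged)

        repaired = repair_outliers(frames)
        for t, rep in enumerate(repaired):
            np.testing.assert_allclose(rep.xy, expect[t])
            assert rep.repaired == frozenset(expected_sets[t])

    def test_idempotent(self):
        frames = _sequence(40, jitter=2.0, seed=2)
        frames[7].xy[JOINT_INDEX["left_wrist"]] += 500.0
        once = repair_outliers(frames)
        twice = repair_outliers(once)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.xy, b.xy)
            assert b.repaired == frozenset()

    def test_invalid_first_frame_raises(self):
        frames = _sequence(5)
        frames[0] = SkeletonFrame(0, 0, np.zeros((17, 2)), np.zeros(17))
        with pytest.raises(CalibrationError, match="lead-in"):
            repair_outliers(frames)


class TestDistanceMatrix:
    def test_diagonal_zero_and_pythagoras(self):
        frame = seated_frame(nose=(0.0, 0.0), left_eye=(3.0, 4.0))
        d = distance_matrix(frame)
        assert d.between("nose", "nose") == 0.0
        assert d.between("nose", "left_eye") == pytest.approx(5.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(7)
        frame = SkeletonFrame(0, 0, rng.uniform(0, 500, (17, 2)), np.full(17, 0.9))
        d = distance_matrix(frame).d
        for i in range(17):
            for j in range(17):
                expect = np.hypot(*(frame.xy[i] - frame.xy[j]))
                assert d[i, j] == pytest.approx(expect)
        np.testing.assert_allclose(d, d.T)

    def test_translation_invariant_scale_equivariant(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            xy = rng.uniform(0, 500, (17, 2))
            shift = rng.uniform(0, 100, 2)
            scale = rng.uniform(0.5, 3.0)
            d0 = distance_matrix(SkeletonFrame(0, 0, xy, np.ones(17))).d
            d1 = distance_matrix(SkeletonFrame(0, 0, xy + shift, np.ones(17))).d
            d2 = distance_matrix(SkeletonFrame(0, 0, xy * scale, np.ones(17))).d
            np.testing.assert_allclose(d1, d0, atol=1e-9)
            np.testing.assert_allclose(d2, d0 * scale, rtol=1e-12)


class TestGeometricFeatures:
    def test_level_nose_gives_zero_tilt(self):
        feat = geometric_features(seated_frame())
        assert feat.head_tilt_deg == pytest.approx(0.0)
        assert feat.shoulder_width == pytest.approx(100.0)

    def test_nose_above_and_behind_gives_45_degrees(self):
        # ear midpoint (320, 150); nose 10 px behind, 10 px above
        frame = seated_frame(nose=(330.0, 140.0))
        assert geometric_features(frame).head_tilt_deg == pytest.approx(45.0)

    def test_matches_scalar_rederivation(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            xy = rng.uniform(10, 500, (17, 2))
            frame = SkeletonFrame(0, 0, xy, np.full(17, 0.9))
            feat = geometric_features(frame)

            def at(name):
                return xy[JOINT_INDEX[name]]

            assert feat.shoulder_width == pytest.approx(
                np.hypot(*(at("left_shoulder") - at("right_shoulder")))
            )
            assert feat.elbow_spread == pytest.approx(
                np.hypot(*(at("left_elbow") - at("right_elbow")))
            )
            assert feat.hip_height == pytest.approx(
                (at("left_hip")[1] + at("right_hip")[1]) / 2
            )
            ear_mid = (at("left_ear") + at("right_ear")) / 2
            expect = np.degrees(
                np.arctan2(ear_mid[1] - at("nose")[1], abs(at("nose")[0] - ear_mid[0]))
            )
            assert feat.head_tilt_deg == pytest.approx(expect)
            assert -90 < feat.head_tilt_deg < 90

    def test_zero_shoulder_width_rejected(self):
        frame = seated_frame(left_shoulder=(300.0, 200.0), right_shoulder=(300.0, 200.0))
        with pytest.raises(ValidationError, match="degenerate"):
            geometric_features(frame)
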