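"""Keypoint-stream repair and per-frame skeletal geometry.

The pose estimator occasionally misplaces single joints (outliers) or loses
the person entirely for a frame. Both are repaired causally: a joint whose
confidence is too low, or whose single-frame displacement is implausibly
large relative to the person's shoulder width, is replaced by its value in
the preceding frame. From the repaired stream we compute, per frame, the
symmetric 17x17 joint distance matrix and the scalar geometric features the
behavior classifiers consume.

Image convention throughout: origin at top-left, y increases downward, so
"higher in the image" means smaller y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ValidationError
from .io_streams import COCO_JOINTS, JOINT_INDEX

N_JOINTS = len(COCO_JOINTS)


@dataclass
class SkeletonFrame:
    """One person's repaired 17-joint skeleton at one frame.

    ``xy`` is a (17, 2) float array in COCO joint order; ``score`` the
    corresponding confidences; ``repaired`` names the joints replaced by the
    outlier repair at this frame.
    """

    frame_index: int
    time_ms: int
    xy: np.ndarray
    score: np.ndarray
    repaired: frozenset = frozenset()

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if self.xy.shape != (N_JOINTS, 2) or self.score.shape != (N_JOINTS,):
            raise ValidationError(
                f"frame {self.frame_index}: expected (17, 2) coordinates and 17 scores"
            )
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError(f"frame {self.frame_index}: non-finite coordinates")

    @property
    def joints(self) -> dict:
        """Mapping joint name -> (x, y, score)."""
        return {
            name: (self.xy[i, 0], self.xy[i, 1], self.score[i])
            for i, name in enumerate(COCO_JOINTS)
        }

    def joint(self, name: str) -> np.ndarray:
        return self.xy[JOINT_INDEX[name]]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric 17x17 Euclidean pixel-distance table for one frame."""

    frame_index: int
    d: np.ndarray

    def between(self, a: str, b: str) -> float:
        return float(self.d[JOINT_INDEX[a], JOINT_INDEX[b]])


@dataclass(frozen=True)
class GeometricFeatures:
    """Scalar geometry of one frame, in pixels/degrees."""

    shoulder_width: float
    elbow_spread: float
    wrist_positions: dict  # "left"/"right" -> (x, y)
    hip_height: float  # mean y of the two hips (image convention: smaller = higher)
    head_tilt_deg: float  # positive when the nose is above the ear line


def frames_from_records(records, fps: float) -> list[SkeletonFrame]:
    """Convert I/O-level keypoint records into SkeletonFrame objects."""
    frames = []
    for rec in records:
        xy = np.zeros((N_JOINTS, 2))
        score = np.zeros(N_JOINTS)
        for i, name in enumerate(COCO_JOINTS):
            x, y, s = rec.joints[name]
            xy[i] = (x, y)
            score[i] = s
        frames.append(
            SkeletonFrame(
                frame_index=rec.frame_index,
                time_ms=int(rec.frame_index * 1000 / fps),
                xy=xy,
                score=score,
            )
        )
    return frames


def median_shoulder_width(frames, score_min: float = 0.3) -> float:
    """Median shoulder distance over frames where both shoulders are confident."""
    ls, rs = JOINT_INDEX["left_shoulder"], JOINT_INDEX["right_shoulder"]
    widths = [
        float(np.linalg.norm(f.xy[ls] - f.xy[rs]))
        for f in frames
        if f.score[ls] >= score_min and f.score[rs] >= score_min
    ]
    if not widths:
        raise CalibrationError(
            "no frame with confident shoulders; cannot establish body scale"
        )
    return float(np.median(widths))


def repair_outliers(frames, jump_threshold: float = 1.0, score_min: float = 0.3):
    """Replace outlier joints by their value in the preceding frame.

    A joint at frame t is an outlier when its confidence is below
    ``score_min`` or its displacement from the (already repaired) frame t-1
    exceeds ``jump_threshold`` times the session's median shoulder width.
    Consecutive outliers chain-copy the last valid value. The first frame
    must itself be valid.

    Returns a new frame list of the same length; each frame's ``repaired``
    set names the joints replaced there.
    """
    frames = list(frames)
    if not frames:
        return []
    if np.all(frames[0].score < score_min):
        raise CalibrationError(
            "first frame has no confident joint; start the recording with a "
            "longer lead-in of the seated person"
        )
    msw = median_shoulder_width(frames, score_min)
    max_jump = jump_threshold * msw

    out = [
        SkeletonFrame(
            frames[0].frame_index,
            frames[0].time_ms,
            frames[0].xy.copy(),
            frames[0].score.copy(),
        )
    ]
    for frame in frames[1:]:
        prev = out[-1]
        disp = np.linalg.norm(frame.xy - prev.xy, axis=1)
        bad = (frame.score < score_min) | (disp > max_jump)
        xy = np.where(bad[:, None], prev.xy, frame.xy)
        score = np.where(bad, prev.score, frame.score)
        out.append(
            SkeletonFrame(
                frame.frame_index,
                frame.time_ms,
                xy,
                score,
                frozenset(COCO_JOINTS[i] for i in np.flatnonzero(bad)),
            )
        )
    return out


def distance_matrix(frame: SkeletonFrame) -> DistanceMatrix:
    """The 17x17 many-to-many Euclidean distance table for one frame."""
    diff = frame.xy[:, None, :] - frame.xy[None, :, :]
    return DistanceMatrix(frame.frame_index, np.linalg.norm(diff, axis=2))


def geometric_features(frame: SkeletonFrame) -> GeometricFeatures:
    """Derive the classifier features from one repaired frame.

    Head tilt is the signed angle between the ear-midpoint-to-nose vector and
    the image horizontal: positive when the nose sits above (smaller y than)
    the ear midpoint, negative below, using the horizontal distance magnitude
    so the sign does not depend on which way the person faces.
    """
    ls = frame.joint("left_shoulder")
    rs = frame.joint("right_shoulder")
    shoulder_width = float(np.linalg.norm(ls - rs))
    if shoulder_width == 0.0:
        raise ValidationError(
            f"frame {frame.frame_index}: degenerate geometry (zero shoulder width)"
        )
    elbow_spread = float(
        np.linalg.norm(frame.joint("left_elbow") - frame.joint("right_elbow"))
    )
    hips = (frame.joint("left_hip") + frame.joint("right_hip")) / 2.0
    ear_mid = (frame.joint("left_ear") + frame.joint("right_ear")) / 2.0
    nose = frame.joint("nose")
    dy = ear_mid[1] - nose[1]  # positive = nose higher in the image
    dx = abs(nose[0] - ear_mid[0])
    head_tilt_deg = math.degrees(math.atan2(dy, dx))
    return GeometricFeatures(
        shoulder_width=shoulder_width,
        elbow_spread=elbow_spread,
        wrist_positions={
            "left": tuple(frame.joint("left_wrist")),
            "right": tuple(frame.joint("right_wrist")),
        },
        hip_height=float(hips[1]),
        head_tilt_deg=head_tilt_deg,
    )
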