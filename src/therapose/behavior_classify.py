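"""Rule-based assignment of the six behavioral attributes to every frame.

Each attribute is a small geometric decision on the repaired skeleton,
normalized by the person's body scale (shoulder width, shoulder-to-hip
length) so the cutoffs are camera-distance-free:

* body pose   — sitting unless the hip midpoint has risen from the seated
                baseline by more than a fraction of the torso length;
* self-touch  — a wrist within a fraction of the shoulder width of the head/
                shoulder landmarks (head & upper torso) or of the hips/torso
                midpoint (middle torso), tracked separately while playing;
* playing hand— which wrists sit inside the keyboard span while notes sound;
* head pose   — the nose's signed elevation over the ear line against a
                symmetric up/down band;
* torso pose  — elbow spread relative to shoulder width, defined only while
                playing with both hands, neutral otherwise.

Label streams are then smoothed by merging sub-threshold runs into their
longer neighbor, and the cross-attribute invariants are re-established.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import CalibrationError, ConfigurationError, ValidationError
from .skeleton_features import (
    DistanceMatrix,
    GeometricFeatures,
    SkeletonFrame,
    distance_matrix,
    geometric_features,
)

BODY_POSES = ("sitting", "standing")
TOUCH_REGIONS = ("head_upper_torso", "middle_torso", "none")
HANDS = ("both", "left", "right", "not_playing")
HEAD_POSES = ("up", "down", "neutral")
TORSO_POSES = ("open", "closed", "neutral")

_HEAD_TARGETS = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
)
_MIDDLE_TARGETS = ("left_hip", "right_hip")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric cutoffs for the per-frame classifiers.

    Ratios are relative to body scale: ``touch_radius_ratio`` to shoulder
    width, ``stand_rise_ratio`` to the shoulder-to-hip length,
    ``torso_*_ratio`` to shoulder width (as elbow_spread / shoulder_width).
    """

    head_tilt_deg_up: float = 15.0
    head_tilt_deg_down: float = -15.0
    torso_open_ratio: float = 1.8
    torso_closed_ratio: float = 1.1
    touch_radius_ratio: float = 0.5
    stand_rise_ratio: float = 0.5
    calibration_s: float = 10.0
    smooth_ms: float = 100.0

    def __post_init__(self):
        if self.head_tilt_deg_up <= self.head_tilt_deg_down:
            raise ValidationError("head up threshold must exceed down threshold")
        if self.torso_open_ratio <= self.torso_closed_ratio:
            raise ValidationError("torso open ratio must exceed closed ratio")
        for name in ("touch_radius_ratio", "stand_rise_ratio", "torso_closed_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class FrameStates:
    """The six behavioral attributes of one frame."""

    frame_index: int
    time_ms: int
    playing: bool
    silent: bool
    body_pose: str
    self_touch: str
    self_touch_while_playing: bool
    playing_hand: str
    head_pose: str
    torso_pose: str

    def validate(self) -> None:
        if self.body_pose not in BODY_POSES:
            raise ValidationError(f"bad body_pose {self.body_pose!r}")
        if self.self_touch not in TOUCH_REGIONS:
            raise ValidationError(f"bad self_touch {self.self_touch!r}")
        if self.playing_hand not in HANDS:
            raise ValidationError(f"bad playing_hand {self.playing_hand!r}")
        if self.head_pose not in HEAD_POSES:
            raise ValidationError(f"bad head_pose {self.head_pose!r}")
        if self.torso_pose not in TORSO_POSES:
            raise ValidationError(f"bad torso_pose {self.torso_pose!r}")
        if (self.playing_hand == "not_playing") != (not self.playing):
            raise ValidationError(
                f"frame {self.frame_index}: playing_hand/playing inconsistent"
            )
        if self.torso_pose in ("open", "closed") and self.playing_hand != "both":
            raise ValidationError(
                f"frame {self.frame_index}: torso {self.torso_pose} without both hands"
            )
        if self.self_touch_while_playing and not (
            self.playing and self.self_touch != "none"
        ):
            raise ValidationError(
                f"frame {self.frame_index}: self_touch_while_playing inconsistent"
            )


def classify_body_pose(
    features: GeometricFeatures,
    sitting_baseline: float,
    torso_length: float,
    thresholds: ClassifierThresholds,
) -> str:
    """Sitting (the default) unless the hips have risen far enough.

    Rising means a *smaller* hip y than the seated baseline, by more than
    ``stand_rise_ratio`` times the median shoulder-to-hip length.
    """
    rise = sitting_baseline - features.hip_height
    return "standing" if rise > thresholds.stand_rise_ratio * torso_length else "sitting"


def classify_self_touch(
    frame: SkeletonFrame,
    d: DistanceMatrix,
    playing: bool,
    thresholds: ClassifierThresholds,
) -> tuple[str, bool]:
    """Which body region (if any) a wrist is touching, and whether while playing."""
    radius = thresholds.touch_radius_ratio * d.between("left_shoulder", "right_shoulder")
    region = "none"
    for wrist in ("left_wrist", "right_wrist"):
        if any(d.between(wrist, t) <= radius for t in _HEAD_TARGETS):
            region = "head_upper_torso"
            break
    if region == "none":
        torso_mid = (
            frame.joint("left_shoulder")
            + frame.joint("right_shoulder")
            + frame.joint("left_hip")
            + frame.joint("right_hip")
        ) / 4.0
        for wrist in ("left_wrist", "right_wrist"):
            near_hip = any(d.between(wrist, t) <= radius for t in _MIDDLE_TARGETS)
            near_mid = (
                float(np.linalg.norm(frame.joint(wrist) - torso_mid)) <= radius
            )
            if near_hip or near_mid:
                region = "middle_torso"
                break
    return region, (region != "none" and playing)


def _in_span(pos, span) -> bool:
    x0, x1, y0, y1 = span
    return x0 <= pos[0] <= x1 and y0 <= pos[1] <= y1


def _dist_to_span(pos, span) -> float:
    x0, x1, y0, y1 = span
    dx = max(x0 - pos[0], 0.0, pos[0] - x1)
    dy = max(y0 - pos[1], 0.0, pos[1] - y1)
    return float(np.hypot(dx, dy))


def classify_playing_hand(
    frame: SkeletonFrame,
    playing: bool,
    keyboard_span,
    occlusion=None,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Which hand(s) are over the keyboard while notes sound.

    A hand is active when its wrist lies inside the keyboard span (an x-range
    and y-band in pixels). If neither wrist qualifies on a playing frame
    (keypoint failure, occlusion), per-partition keyboard-occlusion flags —
    when supplied — vote for the same-side hand; failing that the wrist
    nearest the span is taken, so playing frames always get a hand.
    """
    if not playing:
        return "not_playing"
    if keyboard_span is None:
        raise ConfigurationError(
            "keyboard_span must be configured to classify the playing hand"
        )
    wrists = {
        "left": frame.joint("left_wrist"),
        "right": frame.joint("right_wrist"),
    }
    active = {side for side, pos in wrists.items() if _in_span(pos, keyboard_span)}
    if not active and occlusion is not None:
        # partition 0 = left end of the keyboard (low keys) = left hand side
        sides = ("left", "right")
        n = len(occlusion)
        for i, occ in enumerate(occlusion):
            if occ:
                active.add(sides[0] if i < n / 2 else sides[1])
    if not active:
        nearest = min(wrists, key=lambda s: _dist_to_span(wrists[s], keyboard_span))
        active = {nearest}
    if active == {"left", "right"}:
        return "both"
    return next(iter(active))


def classify_head_pose(
    features: GeometricFeatures, thresholds: ClassifierThresholds
) -> str:
    """Up/down when the nose tilt leaves the neutral band, else neutral."""
    if features.head_tilt_deg > thresholds.head_tilt_deg_up:
        return "up"
    if features.head_tilt_deg < thresholds.head_tilt_deg_down:
        return "down"
    return "neutral"


def classify_torso_pose(
    features: GeometricFeatures,
    playing_hand: str,
    thresholds: ClassifierThresholds,
) -> str:
    """Open/closed elbow spread, defined only while playing with both hands."""
    if playing_hand != "both":
        return "neutral"
    ratio = features.elbow_spread / features.shoulder_width
    if ratio >= thresholds.torso_open_ratio:
        return "open"
    if ratio <= thresholds.torso_closed_ratio:
        return "closed"
    return "neutral"


# ---------------------------------------------------------------------------
# Run-length smoothing


def _runs(labels):
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([start, i - start, labels[start]])
            start = i
    return runs


def smooth_labels(labels, smooth_ms: float, fps: float) -> list:
    """Merge runs shorter than ``smooth_ms`` into their longer neighbor.

    Repeatedly takes the shortest sub-threshold run (earliest on ties) and
    absorbs it into the longer of its neighbors (the preceding one on ties);
    adjacent runs with equal labels coalesce. A stream that is one single run
    is returned unchanged.
    """
    labels = list(labels)
    runs = _runs(labels)
    while len(runs) > 1:
        short = [
            (length, start, idx)
            for idx, (start, length, _) in enumerate(runs)
            if length * 1000 < smooth_ms * fps
        ]
        if not short:
            break
        _, _, idx = min(short)
        if idx == 0:
            target = 1
        elif idx == len(runs) - 1:
            target = idx - 1
        else:
            target = idx - 1 if runs[idx - 1][1] >= runs[idx + 1][1] else idx + 1
        runs[idx][2] = runs[target][2]
        # coalesce equal-label neighbors
        merged = [runs[0]]
        for run in runs[1:]:
            if run[2] == merged[-1][2]:
                merged[-1][1] += run[1]
            else:
                merged.append(run)
        runs = merged
    out = []
    for start, length, label in runs:
        out.extend([label] * length)
    return out


def smooth_states(states, smooth_ms: float, fps: float) -> list[FrameStates]:
    """Smooth each attribute stream independently, then repair the invariants.

    Because the attributes are smoothed independently, a merge can leave e.g.
    a playing frame labeled not_playing; consistency is restored
    deterministically afterwards: the hand on such frames is taken from the
    nearest resolved frame in the same playing run (``both`` if none), torso
    open/closed is demoted to neutral off both-hand frames, and the
    touch-while-playing flag is recomputed.
    """
    if not states:
        return []
    playing = smooth_labels([s.playing for s in states], smooth_ms, fps)
    silent = smooth_labels([s.silent for s in states], smooth_ms, fps)
    body = smooth_labels([s.body_pose for s in states], smooth_ms, fps)
    touch = smooth_labels([s.self_touch for s in states], smooth_ms, fps)
    hand = smooth_labels([s.playing_hand for s in states], smooth_ms, fps)
    head = smooth_labels([s.head_pose for s in states], smooth_ms, fps)
    torso = smooth_labels([s.torso_pose for s in states], smooth_ms, fps)

    hand = _reconcile_hands(playing, hand)
    out = []
    for i, s in enumerate(states):
        torso_i = torso[i]
        if torso_i in ("open", "closed") and hand[i] != "both":
            torso_i = "neutral"
        out.append(
            replace(
                s,
                playing=bool(playing[i]),
                silent=bool(silent[i]),
                body_pose=body[i],
                self_touch=touch[i],
                self_touch_while_playing=bool(playing[i]) and touch[i] != "none",
                playing_hand=hand[i],
                head_pose=head[i],
                torso_pose=torso_i,
            )
        )
    for s in out:
        s.validate()
    return out


def _reconcile_hands(playing, hand):
    """Force playing_hand = not_playing exactly off playing frames."""
    hand = list(hand)
    n = len(hand)
    for i in range(n):
        if not playing[i]:
            hand[i] = "not_playing"
    resolved = [i for i in range(n) if playing[i] and hand[i] != "not_playing"]
    for i in range(n):
        if playing[i] and hand[i] == "not_playing":
            if resolved:
                j = min(resolved, key=lambda r: abs(r - i))
                hand[i] = hand[j]
            else:
                hand[i] = "both"
    return hand


# ---------------------------------------------------------------------------
# Session orchestration


def classify_session(frames, playing, silent, config, occlusion=None):
    """Classify every frame of a repaired skeleton stream.

    ``frames`` are repaired SkeletonFrames; ``playing`` and ``silent`` are
    per-frame booleans from stream_sync; ``occlusion`` an optional per-frame
    sequence of per-partition keyboard-occlusion booleans. The sitting
    baseline and body scale are calibrated from the first
    ``thresholds.calibration_s`` seconds, during which the person is assumed
    seated at the keyboard. Returns smoothed, invariant-checked FrameStates.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("empty frame sequence")
    th = config.thresholds
    n_cal = max(1, int(th.calibration_s * config.fps))
    if len(frames) < n_cal:
        raise CalibrationError(
            f"session shorter than the {th.calibration_s}s calibration window"
        )
    feats = [geometric_features(f) for f in frames]
    baseline = float(np.median([f.hip_height for f in feats[:n_cal]]))
    torso_lengths = []
    for f in frames:
        sh = (f.joint("left_shoulder") + f.joint("right_shoulder")) / 2.0
        hp = (f.joint("left_hip") + f.joint("right_hip")) / 2.0
        torso_lengths.append(float(np.linalg.norm(sh - hp)))
    torso_len = float(np.median(torso_lengths))

    if any(playing) and config.keyboard_span is None:
        raise ConfigurationError(
            "playing frames present but no keyboard_span configured"
        )

    states = []
    for i, (frame, feat) in enumerate(zip(frames, feats)):
        d = distance_matrix(frame)
        is_playing = bool(playing[i])
        hand = classify_playing_hand(
            frame,
            is_playing,
            config.keyboard_span,
            occlusion[i] if occlusion is not None else None,
            th,
        )
        region, while_playing = classify_self_touch(frame, d, is_playing, th)
        states.append(
            FrameStates(
                frame_index=frame.frame_index,
                time_ms=frame.time_ms,
                playing=is_playing,
                silent=bool(silent[i]),
                body_pose=classify_body_pose(feat, baseline, torso_len, th),
                self_touch=region,
                self_touch_while_playing=while_playing,
                playing_hand=hand,
                head_pose=classify_head_pose(feat, th),
                torso_pose=classify_torso_pose(feat, hand, th),
            )
        )
    return smooth_states(states, th.smooth_ms, config.fps)
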