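"""Fully synthetic keyboard-therapy sessions with known ground truth.

The study's recordings cannot be shared, so every pipeline stage is
exercised on sessions generated here: a scripted timeline of behavioral
states is realized as (a) a 17-joint keypoint stream at the video frame
rate, (b) note events covering the scripted playing, (c) audio that is
rendered tone during notes, low-level speech-band noise while talking and a
near-digital floor during scripted silence, and (d) a ground-truth label
CSV (the script sampled on the frame grid).

The skeleton is a seated 2D profile with a 100 px shoulder width and a
150 px shoulder-to-hip length; every pose magnitude is expressed relative
to those, so the default classifier cutoffs are exercised mid-range:

* head tilt is posed at ±45° for up/down against the ±15° cutoffs;
* elbow spread at 1.9 / 1.0 shoulder widths against the 1.8 / 1.1 ratios;
* standing raises the whole skeleton 0.6 torso lengths against the 0.5 cutoff;
* touching wrists land 7 px from their target against the 50 px radius.

Wrists travel between stations (rest, keyboard, head, middle torso) along
fixed waypoint paths whose per-frame steps stay below the outlier-repair
jump threshold (one shoulder width per frame) and outside every self-touch
bubble, and the travel frames are scheduled inside the *inactive*-state
segment adjacent to each transition — so at zero noise the classified state
flips exactly on the scripted boundary frame. Gaussian keypoint jitter and
logged single-frame outlier spikes are then added on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io_streams as io
from .behavior_classify import FrameStates
from .errors import ValidationError
from .io_streams import COCO_JOINTS, JOINT_INDEX, NoteEvent

SAMPLE_RATE = 8000

# -- the seated template, pixels, origin top-left, y down ------------------

_STATIC = {
    "left_eye": (315.0, 143.0),
    "right_eye": (335.0, 143.0),
    "left_ear": (300.0, 150.0),
    "right_ear": (340.0, 150.0),
    "left_shoulder": (270.0, 200.0),
    "right_shoulder": (370.0, 200.0),
    "left_hip": (285.0, 350.0),
    "right_hip": (355.0, 350.0),
    "left_knee": (300.0, 450.0),
    "right_knee": (340.0, 450.0),
    "left_ankle": (300.0, 550.0),
    "right_ankle": (340.0, 550.0),
}

_NOSE = {"neutral": (345.0, 150.0), "up": (345.0, 125.0), "down": (345.0, 175.0)}

_ELBOWS = {
    "neutral": ((250.0, 270.0), (390.0, 270.0)),
    "open": ((225.0, 270.0), (415.0, 270.0)),
    "closed": ((270.0, 270.0), (370.0, 270.0)),
}

_WRIST_STATIONS = {
    "left": {
        "rest": (230.0, 330.0),
        "keyboard": (270.0, 420.0),
        "head": (340.0, 155.0),
        "middle": (280.0, 342.0),
    },
    "right": {
        "rest": (410.0, 330.0),
        "keyboard": (370.0, 420.0),
        "head": (350.0, 145.0),
        "middle": (360.0, 342.0),
    },
}

#: Waypoints from rest to each active station (exclusive of both endpoints).
#: Every per-frame step along a route stays below ~0.8 shoulder widths so
#: that jitter can never push a travel step over the repair jump threshold,
#: and every waypoint keeps > 50 px clearance from all self-touch landmarks.
_ROUTES = {
    "left": {
        "keyboard": ((240.0, 378.0),),
        "head": ((245.0, 270.0), (215.0, 200.0), (225.0, 125.0), (295.0, 95.0)),
        "middle": (),
    },
    "right": {
        "keyboard": ((400.0, 378.0),),
        "head": ((395.0, 270.0), (425.0, 200.0), (415.0, 125.0), (345.0, 90.0)),
        "middle": (),
    },
}

#: Keyboard span (x0, x1, y0, y1) matching the wrist keyboard stations.
KEYBOARD_SPAN = (220.0, 420.0, 400.0, 440.0)

STAND_RISE_PX = 90.0  # 0.6 torso lengths; classifier cutoff is 0.5
SPIKE_STEP_PX = 500.0  # per-axis outlier displacement (7x the jump threshold)

_MIN_RUN_MS = 200
_WRIST_MIN_RUN = 8  # frames
_BODY_WRIST_GAP = 6  # frames


@dataclass(frozen=True)
class Segment:
    """One scripted span of constant behavioral state, half-open [start, end) ms."""

    start_ms: int
    end_ms: int
    body_pose: str = "sitting"
    self_touch: str = "none"
    touch_side: str | None = None
    playing_hand: str = "not_playing"
    head_pose: str = "neutral"
    torso_pose: str = "neutral"
    silent: bool = False

    @property
    def playing(self) -> bool:
        return self.playing_hand != "not_playing"


@dataclass(frozen=True)
class SessionScript:
    """Ground-truth state timeline from which a session is rendered."""

    duration_min: float
    fps: float = 50.0
    segments: tuple = ()
    noise: float = 0.02  # keypoint jitter std, fraction of shoulder width
    spike_rate: float = 2.0  # injected outliers per 1000 frames
    seed: int = 0

    def __post_init__(self):
        _validate_script(self)

    @property
    def duration_ms(self) -> int:
        return int(round(self.duration_min * 60000))

    @property
    def n_frames(self) -> int:
        return int(self.duration_ms * self.fps // 1000)

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.fps

    def states_per_frame(self) -> list[Segment]:
        """The segment governing each frame (sampled at the frame start)."""
        out = []
        seg_iter = iter(self.segments)
        seg = next(seg_iter)
        for f in range(self.n_frames):
            t = f * 1000 / self.fps
            while t >= seg.end_ms:
                seg = next(seg_iter)
            out.append(seg)
        return out

    def ground_truth_states(self) -> list[FrameStates]:
        states = []
        for f, seg in enumerate(self.states_per_frame()):
            playing = seg.playing
            states.append(
                FrameStates(
                    frame_index=f,
                    time_ms=int(f * 1000 / self.fps),
                    playing=playing,
                    silent=seg.silent,
                    body_pose=seg.body_pose,
                    self_touch=seg.self_touch,
                    self_touch_while_playing=playing and seg.self_touch != "none",
                    playing_hand=seg.playing_hand,
                    head_pose=seg.head_pose,
                    torso_pose=seg.torso_pose,
                )
            )
        return states

    def fractions(self) -> dict:
        """Exact per-attribute category time fractions on the frame grid."""
        states = self.ground_truth_states()
        n = len(states)
        out = {"playing": 0.0, "silence": 0.0}
        attrs = {
            "body_pose": ("sitting", "standing"),
            "self_touch": ("head_upper_torso", "middle_torso", "none"),
            "playing_hand": ("both", "left", "right", "not_playing"),
            "head_pose": ("up", "down", "neutral"),
            "torso_pose": ("open", "closed", "neutral"),
        }
        for attr, cats in attrs.items():
            out[attr] = {c: 0.0 for c in cats}
        for s in states:
            out["playing"] += s.playing / n
            out["silence"] += s.silent / n
            for attr in attrs:
                out[attr][getattr(s, attr)] += 1.0 / n
        return out


def _wrist_station(seg: Segment, side: str) -> str:
    hand = seg.playing_hand
    if hand == "both" or hand == side:
        return "keyboard"
    if seg.self_touch != "none" and seg.touch_side == side:
        return "head" if seg.self_touch == "head_upper_torso" else "middle"
    return "rest"


def _runs(values):
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i, values[start]))
            start = i
    return runs


def _validate_script(script: SessionScript) -> None:
    if script.duration_min <= 0 or script.fps <= 0:
        raise ValidationError("duration and fps must be positive")
    if not script.segments:
        raise ValidationError("script has no segments")
    expected = 0
    for seg in script.segments:
        if seg.start_ms != expected:
            raise ValidationError(
                f"segments must tile the session: gap/overlap at {seg.start_ms} ms"
            )
        if seg.end_ms <= seg.start_ms:
            raise ValidationError(f"empty segment at {seg.start_ms} ms")
        for t in (seg.start_ms, seg.end_ms):
            if (t * script.fps) % 1000 != 0:
                raise ValidationError(
                    f"segment boundary {t} ms is not on the frame grid"
                )
        if seg.torso_pose in ("open", "closed") and seg.playing_hand != "both":
            raise ValidationError(
                f"{seg.start_ms} ms: torso {seg.torso_pose} requires both hands"
            )
        if seg.self_touch != "none":
            if seg.playing_hand == "both":
                raise ValidationError(
                    f"{seg.start_ms} ms: self-touch needs a free wrist"
                )
            side = seg.touch_side or (
                "left" if seg.playing_hand == "right" else "right"
            )
            if side == seg.playing_hand:
                raise ValidationError(
                    f"{seg.start_ms} ms: touch_side {side} is the playing hand"
                )
        if seg.silent and seg.playing:
            raise ValidationError(f"{seg.start_ms} ms: a playing segment cannot be silent")
        expected = seg.end_ms
    if expected != script.duration_ms:
        raise ValidationError(
            f"segments end at {expected} ms, session lasts {script.duration_ms} ms"
        )

    per_frame = script.states_per_frame()
    # per-attribute run lengths must survive smoothing and leave room for travel
    min_frames = max(2, int(math.ceil(_MIN_RUN_MS * script.fps / 1000)))
    for attr in ("body_pose", "self_touch", "playing_hand", "head_pose", "torso_pose"):
        for start, end, _ in _runs([getattr(s, attr) for s in per_frame]):
            if end - start < min_frames:
                raise ValidationError(
                    f"{attr} run of {end - start} frames at frame {start} is shorter "
                    f"than {_MIN_RUN_MS} ms"
                )
    for start, end, val in _runs([s.silent for s in per_frame]):
        if val and (end - start) * 1000 < 100 * script.fps:
            raise ValidationError(
                f"scripted silence of {end - start} frames at frame {start} is "
                "shorter than the 100 ms epoch minimum"
            )
    # wrist stations: runs long enough for travel, no active-to-active hops
    body = [s.body_pose for s in per_frame]
    body_changes = {start for start, _, _ in _runs(body)[1:]}
    for side in ("left", "right"):
        stations = [_wrist_station(seg, side) for seg in per_frame]
        station_runs = _runs(stations)
        for i, (start, end, station) in enumerate(station_runs):
            if end - start < _WRIST_MIN_RUN:
                raise ValidationError(
                    f"{side} wrist holds station {station} for only "
                    f"{end - start} frames at frame {start}"
                )
            if i and "rest" not in (station, station_runs[i - 1][2]):
                raise ValidationError(
                    f"{side} wrist hops between active stations "
                    f"({station_runs[i - 1][2]} -> {station}) at frame {start}; "
                    "insert a rest gap in the script"
                )
        for start, _, _ in station_runs[1:]:
            for change in body_changes:
                if abs(start - change) < _BODY_WRIST_GAP:
                    raise ValidationError(
                        f"wrist transition at frame {start} too close to a body-pose "
                        f"change at frame {change}"
                    )
    if per_frame[0].body_pose != "sitting":
        raise ValidationError("sessions must start seated (calibration window)")


# ---------------------------------------------------------------------------
# Realization


def _wrist_path(side: str, s1: str, s2: str):
    """Intermediate points for a station change (endpoints excluded)."""
    routes = _ROUTES[side]
    rest = _WRIST_STATIONS[side]["rest"]
    if s1 == "rest":
        return list(routes[s2])
    if s2 == "rest":
        return list(reversed(routes[s1]))
    return list(reversed(routes[s1])) + [rest] + list(routes[s2])


def _wrist_track(per_frame, side: str) -> np.ndarray:
    stations = [_wrist_station(seg, side) for seg in per_frame]
    coords = _WRIST_STATIONS[side]
    pos = np.array([coords[s] for s in stations], dtype=float)
    runs = _runs(stations)
    for i in range(1, len(runs)):
        b = runs[i][0]
        s1, s2 = runs[i - 1][2], runs[i][2]
        path = _wrist_path(side, s1, s2)
        if not path:
            continue
        if s2 == "rest":
            # leave the active station through the waypoints, arriving later
            for j, p in enumerate(path):
                pos[b + j] = p
        else:
            # approach so the wrist lands on the station exactly at frame b
            for j, p in enumerate(path):
                pos[b - len(path) + j] = p
    return pos


def _rise_track(per_frame) -> np.ndarray:
    rise = np.array(
        [STAND_RISE_PX if seg.body_pose == "standing" else 0.0 for seg in per_frame]
    )
    runs = _runs([seg.body_pose for seg in per_frame])
    for i in range(1, len(runs)):
        b = runs[i][0]
        if runs[i][2] == "standing":  # ease in just before the boundary
            rise[b - 1] = STAND_RISE_PX / 2
        else:  # ease out just after it
            rise[b] = STAND_RISE_PX / 2
    return rise


def render_keypoints(script: SessionScript) -> tuple[np.ndarray, list]:
    """Pose the template per frame; returns (xy array (n, 17, 2), spike log).

    Jitter and spikes are driven by the script's seed; the spike log lists
    (frame_index, joint_name) pairs for repair precision/recall scoring.
    """
    per_frame = script.states_per_frame()
    n = len(per_frame)
    xy = np.zeros((n, len(COCO_JOINTS), 2))
    for name, p in _STATIC.items():
        xy[:, JOINT_INDEX[name]] = p
    xy[:, JOINT_INDEX["nose"]] = [_NOSE[seg.head_pose] for seg in per_frame]
    elbow_key = [
        seg.torso_pose if seg.playing_hand == "both" else "neutral"
        for seg in per_frame
    ]
    xy[:, JOINT_INDEX["left_elbow"]] = [_ELBOWS[k][0] for k in elbow_key]
    xy[:, JOINT_INDEX["right_elbow"]] = [_ELBOWS[k][1] for k in elbow_key]
    xy[:, JOINT_INDEX["left_wrist"]] = _wrist_track(per_frame, "left")
    xy[:, JOINT_INDEX["right_wrist"]] = _wrist_track(per_frame, "right")
    xy[:, :, 1] -= _rise_track(per_frame)[:, None]

    rng = np.random.default_rng(script.seed)
    jitter_rng = np.random.default_rng(rng.integers(2**31))
    spike_rng = np.random.default_rng(rng.integers(2**31))
    if script.noise > 0:
        xy += jitter_rng.normal(0.0, script.noise * 100.0, xy.shape)

    spike_log = []
    n_spikes = int(round(script.spike_rate * n / 1000.0))
    if n_spikes and n > 1:
        frames = spike_rng.choice(np.arange(1, n), size=min(n_spikes, n - 1), replace=False)
        joints = spike_rng.integers(0, len(COCO_JOINTS), size=len(frames))
        for f, j in zip(frames, joints):
            dx = SPIKE_STEP_PX if xy[f, j, 0] < 750 else -SPIKE_STEP_PX
            dy = SPIKE_STEP_PX if xy[f, j, 1] < 750 else -SPIKE_STEP_PX
            xy[f, j] += (dx, dy)
            spike_log.append((int(f), COCO_JOINTS[j]))
        spike_log.sort()
    np.clip(xy, 0.0, None, out=xy)
    return xy, spike_log


def render_notes(script: SessionScript) -> list[NoteEvent]:
    """One sustained note per contiguous scripted playing run."""
    per_frame = script.states_per_frame()
    notes = []
    pitches = (60, 64, 67, 72)
    for i, (start, end, playing) in enumerate(
        _runs([seg.playing for seg in per_frame])
    ):
        if playing:
            notes.append(
                NoteEvent(
                    int(start * 1000 / script.fps),
                    int(end * 1000 / script.fps),
                    pitches[i % len(pitches)],
                    80,
                )
            )
    return notes


def render_audio(script: SessionScript, notes) -> np.ndarray:
    """Tone during notes (-12 dBFS), talk noise (-30 dBFS), floor (-80 dBFS)."""
    n_samples = script.duration_ms * SAMPLE_RATE // 1000
    rng = np.random.default_rng(script.seed + 1)
    audio = rng.normal(0.0, 1e-4, n_samples)  # -80 dBFS floor
    per_frame = script.states_per_frame()
    talk_amp = 10 ** (-30 / 20)
    for start, end, seg_key in _runs(
        [(seg.playing, seg.silent) for seg in per_frame]
    ):
        playing, silent = seg_key
        a = int(start * 1000 / script.fps) * SAMPLE_RATE // 1000
        b = int(end * 1000 / script.fps) * SAMPLE_RATE // 1000
        if not playing and not silent:
            audio[a:b] += rng.normal(0.0, talk_amp, b - a)
    tone_amp = 10 ** (-12 / 20)
    t = np.arange(n_samples) / SAMPLE_RATE
    for note in notes:
        a = note.onset_ms * SAMPLE_RATE // 1000
        b = note.offset_ms * SAMPLE_RATE // 1000
        freq = 440.0 * 2 ** ((note.pitch - 69) / 12)
        audio[a:b] += tone_amp * np.sin(2 * np.pi * freq * t[a:b])
    return audio


@dataclass(frozen=True)
class SyntheticSession:
    script: SessionScript
    paths: dict
    spike_log: tuple
    states: tuple  # ground-truth FrameStates


def generate(
    script: SessionScript,
    out_dir,
    emit_midi: bool = False,
    emit_therapist: bool = False,
) -> SyntheticSession:
    """Write the full synthetic bundle for one scripted session.

    Emits keypoint JSON, a note-event TSV (plus an SMF when ``emit_midi``),
    WAV audio and the ground-truth label CSV into ``out_dir``. With
    ``emit_therapist`` a second, static person (id 1) is included in the
    keypoint file to exercise person selection. Identical scripts (same
    seed) produce byte-identical artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    xy, spike_log = render_keypoints(script)
    n = xy.shape[0]

    therapist = None
    if emit_therapist:
        shift = np.array([600.0, 0.0])
        t_xy = np.array(
            [_STATIC.get(name, _NOSE["neutral"]) for name in COCO_JOINTS]
        )
        t_xy[JOINT_INDEX["nose"]] = _NOSE["neutral"]
        t_xy[JOINT_INDEX["left_elbow"]] = _ELBOWS["neutral"][0]
        t_xy[JOINT_INDEX["right_elbow"]] = _ELBOWS["neutral"][1]
        t_xy[JOINT_INDEX["left_wrist"]] = _WRIST_STATIONS["left"]["rest"]
        t_xy[JOINT_INDEX["right_wrist"]] = _WRIST_STATIONS["right"]["rest"]
        therapist = (t_xy + shift).round(3)

    frames_persons = []
    for f in range(n):
        flat = np.column_stack([xy[f], np.full(len(COCO_JOINTS), 0.9)]).ravel()
        persons = [(0, flat.tolist())]
        if therapist is not None:
            t_flat = np.column_stack(
                [therapist, np.full(len(COCO_JOINTS), 0.9)]
            ).ravel()
            persons.append((1, t_flat.tolist()))
        frames_persons.append(persons)

    paths = {
        "keypoints": out_dir / "keypoints.json",
        "events": out_dir / "notes.tsv",
        "audio": out_dir / "audio.wav",
        "labels": out_dir / "labels.csv",
    }
    io.write_keypoints(paths["keypoints"], frames_persons)
    notes = render_notes(script)
    io.write_note_events(paths["events"], notes)
    if emit_midi:
        paths["midi"] = out_dir / "notes.mid"
        io.write_note_events(paths["midi"], notes)
    io.write_wav(paths["audio"], render_audio(script, notes), SAMPLE_RATE)
    states = script.ground_truth_states()
    io.write_frame_states(states, paths["labels"])
    return SyntheticSession(script, paths, tuple(spike_log), tuple(states))


# ---------------------------------------------------------------------------
# Script construction


def _largest_remainder(n: int, pcts: dict) -> dict:
    """Integer frame counts per category whose sum is exactly n.

    ``pcts`` maps category -> percentage; the residual (100 - sum) goes to a
    ``None`` key the caller interprets as the default category.
    """
    items = list(pcts.items()) + [(None, 100.0 - sum(pcts.values()))]
    raw = {k: n * p / 100.0 for k, p in items}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    shortfall = n - sum(counts.values())
    by_frac = sorted(items, key=lambda kv: -(raw[kv[0]] - counts[kv[0]]))
    for k, _ in by_frac[:shortfall]:
        counts[k] += 1
    return counts


@dataclass
class _Channels:
    """Per-frame attribute arrays assembled before compositing into segments."""

    n: int
    hand: list = None
    silent: list = None
    body: list = None
    touch: list = None
    touch_side: list = None
    head: list = None
    torso: list = None

    def __post_init__(self):
        self.hand = ["not_playing"] * self.n
        self.silent = [False] * self.n
        self.body = ["sitting"] * self.n
        self.touch = ["none"] * self.n
        self.touch_side = [None] * self.n
        self.head = ["neutral"] * self.n
        self.torso = ["neutral"] * self.n


def _fill(arr, start, length, value):
    arr[start : start + length] = [value] * length


def build_script(
    duration_min: float,
    budgets: dict,
    fps: float = 50.0,
    noise: float = 0.02,
    spike_rate: float = 2.0,
    seed: int = 0,
) -> SessionScript:
    """Deterministically lay out a session matching percentage budgets.

    ``budgets`` keys (all percentages of session time, omit for 0):
    ``both``, ``left``, ``right`` (playing hands), ``silence``, ``standing``,
    ``touch_head`` with ``touch_head_playing`` sub-part, ``touch_middle``,
    ``head_up``, ``head_down``, ``torso_open``, ``torso_closed``.

    Layout: not-playing gaps alternate with one bout per playing hand
    (right, both, left); silence fills the gaps front to back; touches and
    the standing spell are centered inside gaps (the while-playing head
    touch inside the right-hand bout, touched by the left wrist). Realized
    fractions equal the budgets to within one frame grid cell
    (largest-remainder rounding).
    """
    duration_ms = int(round(duration_min * 60000))
    n = int(duration_ms * fps // 1000)
    ch = _Channels(n)

    hand_counts = _largest_remainder(
        n,
        {
            "right": budgets.get("right", 0.0),
            "both": budgets.get("both", 0.0),
            "left": budgets.get("left", 0.0),
        },
    )
    np_total = hand_counts[None]
    bouts = [h for h in ("right", "both", "left") if hand_counts[h] > 0]
    n_gaps = len(bouts) + 1
    gap = np_total // n_gaps
    gaps = [gap] * (n_gaps - 1) + [np_total - gap * (n_gaps - 1)]

    cursor = 0
    gap_spans = []
    bout_spans = {}
    for i, bout in enumerate(bouts):
        gap_spans.append((cursor, cursor + gaps[i]))
        cursor += gaps[i]
        bout_spans[bout] = (cursor, cursor + hand_counts[bout])
        _fill(ch.hand, cursor, hand_counts[bout], bout)
        cursor += hand_counts[bout]
    gap_spans.append((cursor, cursor + gaps[-1]))

    # silence fills the gaps front to back; keep every block >= 100 ms
    min_silence = max(1, int(math.ceil(100 * fps / 1000)))
    silence_left = _largest_remainder(n, {"s": budgets.get("silence", 0.0)})["s"]
    for g_start, g_end in gap_spans:
        if silence_left <= 0:
            break
        take = min(silence_left, g_end - g_start)
        if 0 < silence_left - take < min_silence:
            take = max(0, silence_left - min_silence)
        _fill(ch.silent, g_start, take, True)
        silence_left -= take

    def centered(span, length, margin):
        start = span[0] + max(margin, (span[1] - span[0] - length) // 2)
        return min(start, span[1] - margin - length)

    stand = _largest_remainder(n, {"s": budgets.get("standing", 0.0)})["s"]
    if stand:
        span = gap_spans[-1]
        start = centered(span, stand, _BODY_WRIST_GAP + 2)
        _fill(ch.body, start, stand, "standing")

    touch_head = _largest_remainder(n, {"t": budgets.get("touch_head", 0.0)})["t"]
    touch_head_playing = _largest_remainder(
        n, {"t": budgets.get("touch_head_playing", 0.0)}
    )["t"]
    touch_head_playing = min(touch_head_playing, touch_head)
    touch_middle = _largest_remainder(n, {"t": budgets.get("touch_middle", 0.0)})["t"]

    if touch_head_playing:
        if "right" not in bout_spans:
            raise ValidationError(
                "touch_head_playing requires a right-hand playing budget"
            )
        span = bout_spans["right"]
        start = centered(span, touch_head_playing, _WRIST_MIN_RUN + 2)
        _fill(ch.touch, start, touch_head_playing, "head_upper_torso")
        _fill(ch.touch_side, start, touch_head_playing, "left")
    rest_head = touch_head - touch_head_playing
    if rest_head:
        span = gap_spans[1] if len(gap_spans) > 1 else gap_spans[0]
        start = centered(span, rest_head, _WRIST_MIN_RUN + 2)
        _fill(ch.touch, start, rest_head, "head_upper_torso")
        _fill(ch.touch_side, start, rest_head, "right")
    if touch_middle:
        span = gap_spans[min(2, len(gap_spans) - 1)]
        start = centered(span, touch_middle, _WRIST_MIN_RUN + 2)
        _fill(ch.touch, start, touch_middle, "middle_torso")
        _fill(ch.touch_side, start, touch_middle, "right")

    head_counts = _largest_remainder(
        n,
        {"up": budgets.get("head_up", 0.0), "down": budgets.get("head_down", 0.0)},
    )
    neutral = head_counts[None]
    thirds = [neutral // 3, neutral // 3, neutral - 2 * (neutral // 3)]
    cursor = thirds[0]
    if head_counts["up"]:
        _fill(ch.head, cursor, head_counts["up"], "up")
    cursor += head_counts["up"] + thirds[1]
    if head_counts["down"]:
        _fill(ch.head, cursor, head_counts["down"], "down")

    torso_open = _largest_remainder(n, {"t": budgets.get("torso_open", 0.0)})["t"]
    torso_closed = _largest_remainder(n, {"t": budgets.get("torso_closed", 0.0)})["t"]
    if torso_open or torso_closed:
        span = bout_spans.get("both")
        if span is None or (span[1] - span[0]) < torso_open + torso_closed:
            raise ValidationError(
                "torso open/closed budgets exceed the both-hands playing budget"
            )
        _fill(ch.torso, span[0], torso_open, "open")
        _fill(ch.torso, span[1] - torso_closed, torso_closed, "closed")

    # composite segments at every channel boundary
    keys = list(
        zip(ch.hand, ch.silent, ch.body, ch.touch, ch.touch_side, ch.head, ch.torso)
    )
    segments = []
    for start, end, key in _runs(keys):
        hand, silent, body, touch, side, head, torso = key
        segments.append(
            Segment(
                start_ms=int(start * 1000 / fps),
                end_ms=int(end * 1000 / fps),
                body_pose=body,
                self_touch=touch,
                touch_side=side,
                playing_hand=hand,
                head_pose=head,
                torso_pose=torso,
                silent=silent,
            )
        )
    return SessionScript(
        duration_min=duration_min,
        fps=fps,
        segments=tuple(segments),
        noise=noise,
        spike_rate=spike_rate,
        seed=seed,
    )


#: Published per-session percentage profiles of the two case-study subjects.
#: "~0" table cells are taken as 0.25 (nonzero but rounding to 0); within
#: each profile the playing total is the sum of the per-hand percentages, and
#: the no-self-touch share is the residual, so the frame-level invariants
#: hold exactly (the printed table rounds each cell independently).
PUBLISHED_PROFILES = {
    "subjectA_first": {
        "both": 17.0, "left": 1.0, "right": 18.0,
        "silence": 17.0, "standing": 0.25,
        "touch_head": 3.0, "touch_head_playing": 0.25, "touch_middle": 0.25,
        "head_up": 4.0, "head_down": 3.0,
        "torso_open": 16.0, "torso_closed": 0.25,
    },
    "subjectA_last": {
        "both": 23.0, "left": 0.25, "right": 6.0,
        "silence": 41.0, "standing": 0.25,
        "touch_head": 1.0, "touch_head_playing": 0.25, "touch_middle": 0.25,
        "head_up": 1.0, "head_down": 2.0,
        "torso_open": 21.0, "torso_closed": 2.0,
    },
    "subjectB_first": {
        "both": 8.0, "left": 0.25, "right": 27.0,
        "silence": 33.0, "standing": 0.25,
        "touch_head": 3.0, "touch_head_playing": 0.25, "touch_middle": 0.25,
        "head_up": 0.0, "head_down": 49.0,
        "torso_open": 7.0, "torso_closed": 0.25,
    },
    "subjectB_last": {
        "both": 5.0, "left": 0.25, "right": 34.0,
        "silence": 50.0, "standing": 1.0,
        "touch_head": 9.0, "touch_head_playing": 3.0, "touch_middle": 0.25,
        "head_up": 0.25, "head_down": 88.0,
        "torso_open": 5.0, "torso_closed": 0.0,
    },
}


def published_profile_script(
    profile: str,
    duration_min: float = 50.0,
    fps: float = 50.0,
    noise: float = 0.02,
    spike_rate: float = 2.0,
    seed: int = 0,
) -> SessionScript:
    """A script whose attribute time fractions follow a published profile."""
    if profile not in PUBLISHED_PROFILES:
        raise LookupError(
            f"unknown profile {profile!r}; available: {sorted(PUBLISHED_PROFILES)}"
        )
    return build_script(
        duration_min,
        PUBLISHED_PROFILES[profile],
        fps=fps,
        noise=noise,
        spike_rate=spike_rate,
        seed=seed,
    )
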