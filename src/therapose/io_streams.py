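"""Readers and writers for every external format the pipeline touches.

Inputs: COCO-style keypoint JSON from a pose estimator, note-event tables
(TSV or Standard MIDI File), silence annotations (Praat TextGrid or a plain
start/end TSV), and mono PCM WAV audio. Outputs: the per-frame state CSV and
the per-session summary JSON. All readers normalize into the internal data
model and enforce the type invariants at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import smf
from .errors import FormatError, PersonLookupError, ValidationError

#: The 17 COCO keypoint names, in the order pose estimators emit them as a
#: flat [x0, y0, s0, x1, y1, s1, ...] array.
COCO_JOINTS = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

JOINT_INDEX = {name: i for i, name in enumerate(COCO_JOINTS)}


@dataclass(frozen=True)
class KeypointRecord:
    """One tracked person's 17 keypoints at one video frame."""

    frame_index: int
    person_id: int
    joints: dict  # joint name -> (x, y, score)

    def __post_init__(self):
        if set(self.joints) != set(COCO_JOINTS):
            missing = set(COCO_JOINTS) - set(self.joints)
            extra = set(self.joints) - set(COCO_JOINTS)
            raise ValidationError(
                f"frame {self.frame_index}: joint names must be the 17 COCO names "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        for name, (x, y, s) in self.joints.items():
            if not (math.isfinite(x) and math.isfinite(y)) or x < 0 or y < 0:
                raise ValidationError(
                    f"frame {self.frame_index}: joint {name} has bad coordinates ({x}, {y})"
                )
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"frame {self.frame_index}: joint {name} score {s} outside [0, 1]"
                )


@dataclass(frozen=True)
class NoteEvent:
    """A closed note: half-open [onset_ms, offset_ms) sounding interval."""

    onset_ms: int
    offset_ms: int
    pitch: int
    velocity: int

    def __post_init__(self):
        if self.onset_ms < 0:
            raise ValidationError(f"negative onset {self.onset_ms}")
        if self.offset_ms <= self.onset_ms:
            raise ValidationError(
                f"note offset {self.offset_ms} not after onset {self.onset_ms}"
            )
        if not 0 <= self.pitch <= 127 or not 0 <= self.velocity <= 127:
            raise ValidationError(
                f"pitch/velocity ({self.pitch}, {self.velocity}) outside 0..127"
            )


@dataclass(frozen=True)
class IntervalTier:
    """Sorted, non-overlapping half-open [start, end) intervals within a session."""

    intervals: tuple  # of (start_ms, end_ms, label)
    duration_ms: int

    def __post_init__(self):
        prev_end = 0
        for start, end, _label in self.intervals:
            if end <= start:
                raise ValidationError(f"interval ({start}, {end}) has end <= start")
            if start < prev_end:
                raise ValidationError(
                    f"interval starting at {start} overlaps previous ending at {prev_end}"
                )
            if start < 0 or end > self.duration_ms:
                raise ValidationError(
                    f"interval ({start}, {end}) outside [0, {self.duration_ms})"
                )
            prev_end = end

    def total_ms(self) -> int:
        return sum(end - start for start, end, _ in self.intervals)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything that parameterizes one analysis run.

    The classifier cutoffs live in :class:`~therapose.behavior_classify.
    ClassifierThresholds`; this object adds the stream-level settings: frame
    rate, outlier repair, silence detection, the keyboard geometry, and how
    percentages are printed.
    """

    fps: float = 50.0
    person_id: int = 0
    # outlier repair
    jump_threshold: float = 1.0  # fraction of median shoulder width per frame
    score_min: float = 0.3
    # silence detection
    silence_window_ms: int = 20
    silence_threshold_db: float = -40.0
    min_silence_ms: int = 100
    midi_offset_ms: int = 0
    # keyboard geometry: wrist span for playing-hand, pixel rect for images
    keyboard_span: tuple | None = None  # (x0, x1, y0, y1)
    keyboard_region: tuple | None = None  # (x0, y0, x1, y1) image rect
    white_tolerance: int = 60
    rounding: str = "half_up"
    thresholds: "object" = None  # ClassifierThresholds; late default below

    def __post_init__(self):
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        for name in ("jump_threshold", "silence_window_ms", "min_silence_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.thresholds is None:
            from .behavior_classify import ClassifierThresholds

            self.thresholds = ClassifierThresholds()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .behavior_classify import ClassifierThresholds

        d = dict(d)
        thresholds = d.pop("thresholds", None)
        for key in ("keyboard_span", "keyboard_region"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if thresholds is not None:
            cfg.thresholds = ClassifierThresholds(**thresholds)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Keypoints


def _frame_obj_records(obj, frame_pos):
    if not isinstance(obj, dict) or "persons" not in obj:
        raise FormatError(f"frame {frame_pos}: expected an object with a 'persons' list")
    return obj.get("frame_index", frame_pos), obj["persons"]


def read_keypoints(path, person_id: int):
    """Read a keypoint file and return one ``KeypointRecord`` per frame.

    Accepts either a single JSON array of frame objects or line-delimited
    JSON (one frame object per line). Each frame object is
    ``{"frame_index": int, "persons": [{"person_id": int, "keypoints":
    [x0, y0, s0, ...]}]}`` with 17*3 keypoint values in COCO order. Frames
    where the person is missing are emitted with all scores zero so the
    timeline stays dense for downstream repair.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    frames = []
    if stripped.startswith("["):
        try:
            frames = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    else:
        for lineno, line in enumerate(text.splitlines()):
            if not line.strip():
                continue
            try:
                frames.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise FormatError(
                    f"{path}: malformed JSON at frame {lineno}: {exc}"
                ) from exc

    seen_ids = set()
    by_frame = {}
    for pos, obj in enumerate(frames):
        try:
            frame_index, persons = _frame_obj_records(obj, pos)
        except FormatError:
            raise
        for person in persons:
            try:
                pid = person["person_id"]
                flat = person["keypoints"]
            except (TypeError, KeyError) as exc:
                raise FormatError(
                    f"{path}: frame {pos}: person entry missing {exc}"
                ) from exc
            seen_ids.add(pid)
            if pid != person_id:
                continue
            if len(flat) != 3 * len(COCO_JOINTS):
                raise FormatError(
                    f"{path}: frame {pos}: expected {3 * len(COCO_JOINTS)} keypoint "
                    f"values, got {len(flat)}"
                )
            joints = {
                name: (float(flat[3 * i]), float(flat[3 * i + 1]), float(flat[3 * i + 2]))
                for i, name in enumerate(COCO_JOINTS)
            }
            by_frame[int(frame_index)] = joints

    if person_id not in seen_ids:
        raise PersonLookupError(person_id, seen_ids)

    n_frames = len(frames)
    empty = {name: (0.0, 0.0, 0.0) for name in COCO_JOINTS}
    return [
        KeypointRecord(f, person_id, by_frame.get(f, dict(empty)))
        for f in range(n_frames)
    ]


def write_keypoints(path, frames_persons) -> None:
    """Write keypoints as a JSON array of frame objects.

    ``frames_persons`` is a sequence (per frame) of lists of
    ``(person_id, flat_keypoints)`` pairs; flat arrays are 17*3 in COCO order.
    """
    out = []
    for f, persons in enumerate(frames_persons):
        out.append(
            {
                "frame_index": f,
                "persons": [
                    {"person_id": pid, "keypoints": [round(float(v), 3) for v in flat]}
                    for pid, flat in persons
                ],
            }
        )
    Path(path).write_text(json.dumps(out))


# ---------------------------------------------------------------------------
# Note events


def read_note_events(path) -> list[NoteEvent]:
    """Read note events from a Standard MIDI File or an onset/offset TSV.

    TSV columns: onset_ms, offset_ms, pitch, velocity (header optional).
    Events come back sorted by onset; in MIDI, note-on with velocity 0 is a
    note-off and unmatched note-ons are closed at the end of the stream.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head == b"MThd":
        return [
            NoteEvent(n.onset_ms, n.offset_ms, n.pitch, n.velocity)
            for n in smf.read_smf(path)
        ]

    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p for p in parts if p != ""]
            if lineno == 1 and not parts[0].lstrip("-").isdigit():
                continue  # header row
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns "
                    "(onset_ms, offset_ms, pitch, velocity)"
                )
            try:
                onset, offset, pitch, velocity = (int(float(p)) for p in parts[:4])
                events.append(NoteEvent(onset, offset, pitch, velocity))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
    events.sort(key=lambda e: (e.onset_ms, e.pitch))
    return events


def write_note_events(path, events) -> None:
    """Write note events; .mid/.midi paths get an SMF, anything else a TSV."""
    path = Path(path)
    if path.suffix.lower() in (".mid", ".midi"):
        smf.write_smf(
            path,
            [smf.RawNote(e.onset_ms, e.offset_ms, e.pitch, e.velocity) for e in events],
        )
        return
    lines = ["onset_ms\toffset_ms\tpitch\tvelocity"]
    lines += [
        f"{e.onset_ms}\t{e.offset_ms}\t{e.pitch}\t{e.velocity}" for e in events
    ]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Silence intervals (TextGrid / TSV)

_SILENT_LABELS = {"silent", "silence", "sil"}


def _parse_textgrid(text, path):
    """Extract (start_s, end_s, label) triples from a long or short TextGrid.

    Only IntervalTier tiers are read; a TextGrid with none raises FormatError.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    intervals = []
    saw_interval_tier = False
    if any(ln.startswith("class = ") or ln.startswith("intervals [") for ln in lines):
        # long format
        in_interval_tier = False
        current = {}
        for ln in lines:
            if ln.startswith("class = "):
                in_interval_tier = '"IntervalTier"' in ln
                saw_interval_tier = saw_interval_tier or in_interval_tier
            elif in_interval_tier and ln.startswith("intervals ["):
                current = {}
            elif in_interval_tier and "=" in ln:
                key, _, value = ln.partition("=")
                key = key.strip()
                value = value.strip()
                if key in ("xmin", "xmax"):
                    current[key] = float(value)
                elif key == "text":
                    current["text"] = value.strip('"')
                    if "xmin" in current and "xmax" in current:
                        intervals.append(
                            (current["xmin"], current["xmax"], current["text"])
                        )
    else:
        # short format: header then per tier: class, name, xmin, xmax, n,
        # then n * (xmin, xmax, text)
        try:
            idx = next(i for i, ln in enumerate(lines) if ln == '"IntervalTier"')
            saw_interval_tier = True
            n = int(float(lines[idx + 4]))
            pos = idx + 5
            for _ in range(n):
                xmin = float(lines[pos])
                xmax = float(lines[pos + 1])
                label = lines[pos + 2].strip('"')
                intervals.append((xmin, xmax, label))
                pos += 3
        except StopIteration:
            pass
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed short TextGrid: {exc}") from exc
    if not saw_interval_tier:
        raise FormatError(f"{path}: no IntervalTier tier found")
    return intervals


def read_intervals(path, duration_ms: int) -> IntervalTier:
    """Read silence intervals from a Praat TextGrid or a start/end TSV.

    TextGrid intervals labeled silent (``silent``/``silence``/``sil``, case
    insensitive) are retained; TSV rows are (start_ms, end_ms) and all rows
    are treated as silent. Intervals are clipped to [0, duration_ms).
    """
    path = Path(path)
    text = path.read_text()
    raw = []
    if "IntervalTier" in text or text.lstrip().startswith("File type"):
        for xmin, xmax, label in _parse_textgrid(text, path):
            if label.strip().lower() in _SILENT_LABELS:
                raw.append((int(round(xmin * 1000)), int(round(xmax * 1000))))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", "\t").split("\t") if p]
            if lineno == 1 and not parts[0].lstrip("-").isdigit():
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected start_ms, end_ms")
            raw.append((int(float(parts[0])), int(float(parts[1]))))

    clipped = []
    for start, end in sorted(raw):
        start = max(0, start)
        end = min(duration_ms, end)
        if end > start:
            clipped.append((start, end, "silent"))
    return IntervalTier(tuple(clipped), duration_ms)


def write_intervals_tsv(path, tier: IntervalTier) -> None:
    lines = ["start_ms\tend_ms"]
    lines += [f"{s}\t{e}" for s, e, _ in tier.intervals]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# WAV audio


def read_wav(path):
    """Read mono PCM WAV; returns (samples as float in [-1, 1], sample_rate)."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, rate


def write_wav(path, samples, rate: int) -> None:
    from scipy.io import wavfile

    pcm = np.clip(np.asarray(samples), -1.0, 1.0)
    wavfile.write(path, rate, (pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Frame states CSV and summary JSON

STATE_COLUMNS = (
    "frame_index",
    "time_ms",
    "playing",
    "silent",
    "body_pose",
    "self_touch",
    "self_touch_while_playing",
    "playing_hand",
    "head_pose",
    "torso_pose",
)


def write_frame_states(states, path) -> None:
    """Write per-frame states as CSV, one row per frame."""
    if not len(states):
        raise ValidationError("cannot write an empty state sequence")
    df = pd.DataFrame(
        {
            "frame_index": [s.frame_index for s in states],
            "time_ms": [s.time_ms for s in states],
            "playing": [int(s.playing) for s in states],
            "silent": [int(s.silent) for s in states],
            "body_pose": [s.body_pose for s in states],
            "self_touch": [s.self_touch for s in states],
            "self_touch_while_playing": [int(s.self_touch_while_playing) for s in states],
            "playing_hand": [s.playing_hand for s in states],
            "head_pose": [s.head_pose for s in states],
            "torso_pose": [s.torso_pose for s in states],
        }
    )
    df.to_csv(path, index=False)


def read_frame_states(path):
    """Read a frame-state CSV back into FrameStates objects."""
    from .behavior_classify import FrameStates

    df = pd.read_csv(path)
    missing = set(STATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        FrameStates(
            frame_index=int(r.frame_index),
            time_ms=int(r.time_ms),
            playing=bool(r.playing),
            silent=bool(r.silent),
            body_pose=str(r.body_pose),
            self_touch=str(r.self_touch),
            self_touch_while_playing=bool(r.self_touch_while_playing),
            playing_hand=str(r.playing_hand),
            head_pose=str(r.head_pose),
            torso_pose=str(r.torso_pose),
        )
        for r in df.itertuples()
    ]


def write_summary(summary, path, config: RunConfig | None = None) -> None:
    """Write a session summary as JSON, echoing the run config for provenance."""
    doc = summary.to_dict()
    if config is not None:
        doc["config"] = config.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_summary(path):
    from .session_summary import SessionSummary

    with open(path) as fh:
        doc = json.load(fh)
    doc.pop("config", None)
    return SessionSummary.from_dict(doc)
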