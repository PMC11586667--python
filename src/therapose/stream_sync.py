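"""Frame timeline construction and projection of MIDI/audio onto it.

The session clock is the video frame grid: frame f covers the half-open
millisecond window [f * 1000/fps, (f+1) * 1000/fps). Note events mark a
frame as *playing* when any sounding note overlaps its window; silence
intervals (detected here by RMS thresholding, or imported from Praat) mark
a frame *silent* when they cover at least half of its window. Frame/window
arithmetic is done in exact integer units of (1/fps) ms to keep boundary
frames unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_streams import IntervalTier


@dataclass(frozen=True)
class FrameTimeline:
    fps: float
    n_frames: int
    duration_ms: int

    def __post_init__(self):
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.n_frames != int(self.duration_ms * self.fps // 1000):
            raise ValidationError(
                f"n_frames {self.n_frames} inconsistent with duration "
                f"{self.duration_ms} ms at {self.fps} fps"
            )

    @classmethod
    def from_duration_ms(cls, duration_ms: int, fps: float) -> "FrameTimeline":
        return cls(fps, int(duration_ms * fps // 1000), duration_ms)

    @classmethod
    def from_frame_count(cls, n_frames: int, fps: float) -> "FrameTimeline":
        # smallest integer duration containing exactly n_frames full windows
        duration_ms = -(-n_frames * 1000 // int(fps)) if float(fps).is_integer() else int(
            np.ceil(n_frames * 1000 / fps)
        )
        return cls(fps, n_frames, duration_ms)


def frames_from_duration(duration_min: float, fps: float) -> int:
    """Number of full video frames in a session of the given length.

    A 50-minute session at the standard 50 fps yields 150,000 frames; an
    hour-long one about 180,000.
    """
    if duration_min <= 0 or fps <= 0:
        raise ValidationError("duration and fps must both be positive")
    return int(duration_min * 60 * fps)


def mark_playing(events, timeline: FrameTimeline, offset_ms: int = 0) -> np.ndarray:
    """Boolean per frame: does any note's [onset, offset) overlap the frame window?

    ``offset_ms`` shifts the event clock onto the video clock. Events
    extending beyond the session are clipped (a warning reports how many).
    """
    playing = np.zeros(timeline.n_frames, dtype=bool)
    fps = timeline.fps
    clipped = 0
    for ev in events:
        onset = ev.onset_ms + offset_ms
        offset = ev.offset_ms + offset_ms
        # frame f overlaps [onset, offset) iff onset < (f+1)*Δ and offset > f*Δ
        f0 = int(onset * fps // 1000)
        f1 = -int(-offset * fps // 1000)  # ceil
        if f1 > timeline.n_frames or f0 < 0:
            clipped += 1
        f0 = max(f0, 0)
        f1 = min(f1, timeline.n_frames)
        if f1 > f0:
            playing[f0:f1] = True
    if clipped:
        warnings.warn(
            f"{clipped} note event(s) extended beyond the session and were clipped",
            stacklevel=2,
        )
    return playing


def detect_silences(
    samples,
    sample_rate: int,
    frame_ms: int = 20,
    rms_threshold_db: float = -40.0,
) -> IntervalTier:
    """Detect silence by RMS thresholding on fixed windows.

    Windows of ``frame_ms`` whose RMS level (dB re full scale 1.0) is below
    ``rms_threshold_db`` are silent; adjacent silent windows merge into
    half-open intervals. A trailing partial window is included in the scan.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("empty audio")
    if frame_ms < 10:
        raise ValidationError(f"frame_ms must be >= 10, got {frame_ms}")
    win = max(1, int(round(sample_rate * frame_ms / 1000)))
    n_win = -(-samples.size // win)
    padded = np.zeros(n_win * win)
    padded[: samples.size] = samples
    rms = np.sqrt(np.mean(padded.reshape(n_win, win) ** 2, axis=1))
    threshold = 10.0 ** (rms_threshold_db / 20.0)
    silent = rms < threshold

    duration_ms = int(round(samples.size * 1000 / sample_rate))
    intervals = []
    start = None
    for i, flag in enumerate(silent):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start * frame_ms, i * frame_ms, "silent"))
            start = None
    if start is not None:
        intervals.append((start * frame_ms, duration_ms, "silent"))
    intervals = [
        (s, min(e, duration_ms), lab) for s, e, lab in intervals if s < duration_ms
    ]
    return IntervalTier(tuple(intervals), duration_ms)


def filter_silence_epochs(tier: IntervalTier, min_ms: int = 100) -> IntervalTier:
    """Drop silence intervals shorter than ``min_ms`` (inclusive threshold:
    an interval of exactly ``min_ms`` is retained)."""
    kept = tuple(iv for iv in tier.intervals if iv[1] - iv[0] >= min_ms)
    return IntervalTier(kept, tier.duration_ms)


def mark_silent(tier: IntervalTier, timeline: FrameTimeline) -> np.ndarray:
    """Boolean per frame: is at least half the frame window covered by silence?

    Coverage is computed exactly in units of 1/fps milliseconds, so frames
    whose boundaries coincide with interval edges are never double counted.
    """
    fps = timeline.fps
    silent = np.zeros(timeline.n_frames, dtype=bool)
    coverage = np.zeros(timeline.n_frames, dtype=float)
    for start, end, _ in tier.intervals:
        # window f is [f*1000, (f+1)*1000) in fps-scaled ms units
        a = start * fps
        b = end * fps
        f0 = int(a // 1000)
        f1 = min(-int(-b // 1000), timeline.n_frames)
        for f in range(max(f0, 0), f1):
            overlap = min(b, (f + 1) * 1000) - max(a, f * 1000)
            coverage[f] += overlap
    silent = coverage * 2 >= 1000
    return silent
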