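"""End-to-end analysis: files in, frame states and session summary out."""

from __future__ import annotations

from pathlib import Path

from . import io_streams as io
from .behavior_classify import classify_session
from .errors import ConfigurationError
from .io_streams import RunConfig
from .session_summary import SessionSummary, summarize
from .skeleton_features import frames_from_records, repair_outliers
from .stream_sync import (
    FrameTimeline,
    detect_silences,
    filter_silence_epochs,
    mark_playing,
    mark_silent,
)


def analyze_session(
    keypoints_path,
    events_path,
    audio_path=None,
    intervals_path=None,
    config: RunConfig | None = None,
    session_id: str = "session",
):
    """Run the full pipeline on one session's input files.

    Silence comes from ``intervals_path`` (TextGrid/TSV) when given,
    otherwise it is detected from ``audio_path``; at least one is required.
    Returns (frame states, session summary).
    """
    config = config or RunConfig()
    records = io.read_keypoints(keypoints_path, config.person_id)
    frames = frames_from_records(records, config.fps)
    repaired = repair_outliers(frames, config.jump_threshold, config.score_min)
    timeline = FrameTimeline.from_frame_count(len(repaired), config.fps)

    events = io.read_note_events(events_path)
    playing = mark_playing(events, timeline, config.midi_offset_ms)

    if intervals_path is not None:
        tier = io.read_intervals(intervals_path, timeline.duration_ms)
    elif audio_path is not None:
        samples, rate = io.read_wav(audio_path)
        tier = detect_silences(
            samples, rate, config.silence_window_ms, config.silence_threshold_db
        )
    else:
        raise ConfigurationError("provide either audio or a silence-interval file")
    tier = filter_silence_epochs(tier, config.min_silence_ms)
    silent = mark_silent(tier, timeline)

    states = classify_session(repaired, playing, silent, config)
    summary = summarize(states, config.fps, session_id)
    return states, summary


def write_outputs(states, summary, out_dir, config: RunConfig | None = None):
    """Write the state CSV and summary JSON; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    states_path = out_dir / "states.csv"
    summary_path = out_dir / "summary.json"
    io.write_frame_states(states, states_path)
    io.write_summary(summary, summary_path, config)
    return states_path, summary_path
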