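"""Frame-grid arithmetic, playing/silence projection, epoch filtering."""

import numpy as np
import pytest

from therapose.errors import ValidationError
from therapose.io_streams import IntervalTier, NoteEvent
from therapose.stream_sync import (
    FrameTimeline,
    detect_silences,
    filter_silence_epochs,
    frames_from_duration,
    mark_playing,
    mark_silent,
)


class TestFrameArithmetic:
    @pytest.mark.parametrize(
        "minutes,fps,expect",
        [(50, 50, 150_000), (60, 50, 180_000), (1, 1, 60)],
    )
    def test_frame_counts(self, minutes, fps, expect):
        assert frames_from_duration(minutes, fps) == expect

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            frames_from_duration(0, 50)
        with pytest.raises(ValidationError):
            frames_from_duration(10, -1)


def _random_events(rng, horizon_ms, n):
    events = []
    for _ in range(n):
        onset = int(rng.integers(0, horizon_ms - 1))
        offset = int(rng.integers(onset + 1, horizon_ms + 200))
        events.append(NoteEvent(onset, offset, 60, 64))
    return events


class TestMarkPlaying:
    def test_note_spanning_two_frame_windows(self):
        timeline = FrameTimeline.from_duration_ms(100, 50)
        flags = mark_playing([NoteEvent(0, 40, 60, 64)], timeline)
        assert flags.tolist() == [True, True, False, False, False]

    def test_no_events_all_false(self):
        timeline = FrameTimeline.from_duration_ms(1000, 50)
        assert not mark_playing([], timeline).any()

    def test_matches_brute_force_overlap(self):
        """200 random event sets equal an O(events x frames) overlap check."""
        rng = np.random.default_rng(13)
        for _ in range(200):
            fps = float(rng.choice([25, 30, 50]))
            n_frames = int(rng.integers(5, 60))
            timeline = FrameTimeline.from_frame_count(n_frames, fps)
            events = _random_events(rng, timeline.duration_ms, int(rng.integers(0, 6)))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                flags = mark_playing(events, timeline)
            for f in range(n_frames):
                w0, w1 = f * 1000 / fps, (f + 1) * 1000 / fps
                expect = any(e.onset_ms < w1 and e.offset_ms > w0 for e in events)
                assert flags[f] == expect

    def test_commutes_with_timeline_split(self):
        rng = np.random.default_rng(14)
        full = FrameTimeline.from_frame_count(40, 50.0)
        events = _random_events(rng, full.duration_ms - 200, 5)
        whole = mark_playing(events, full)
        half_ms = 20 * 20  # 20 frames
        first = FrameTimeline.from_frame_count(20, 50.0)
        second = FrameTimeline.from_frame_count(20, 50.0)

        def clip_shift(lo, hi):
            out = []
            for e in events:
                a, b = max(e.onset_ms, lo), min(e.offset_ms, hi)
                if b > a:
                    out.append(NoteEvent(a - lo, b - lo, e.pitch, e.velocity))
            return out

        joined = np.concatenate(
            [
                mark_playing(clip_shift(0, half_ms), first),
                mark_playing(clip_shift(half_ms, 2 * half_ms), second),
            ]
        )
        np.testing.assert_array_equal(whole, joined)


class TestDetectSilences:
    def test_digital_silence_is_one_interval(self):
        tier = detect_silences(np.zeros(8000), 8000)
        assert tier.intervals == ((0, 1000, "silent"),)

    def test_full_scale_tone_has_no_silence(self):
        t = np.arange(8000) / 8000
        tier = detect_silences(np.sin(2 * np.pi * 440 * t), 8000)
        assert tier.intervals == ()

    def test_constructed_gap_recovered_within_one_window(self):
        rate = 8000
        t = np.arange(rate) / rate
        audio = 0.5 * np.sin(2 * np.pi * 440 * t)
        floor = 10 ** (-60 / 20)
        audio[int(0.5 * rate) : int(0.8 * rate)] = floor * np.sin(
            2 * np.pi * 440 * t[: int(0.3 * rate)]
        )
        tier = detect_silences(audio, rate, frame_ms=20, rms_threshold_db=-40)
        assert len(tier.intervals) == 1
        start, end, _ = tier.intervals[0]
        assert abs(start - 500) <= 20 and abs(end - 800) <= 20

    def test_empty_audio_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            detect_silences(np.array([]), 8000)


class TestFilterEpochs:
    def test_hundred_ms_inclusive_boundary(self):
        tier = IntervalTier(((0, 99, "silent"), (200, 300, "silent")), 1000)
        kept = filter_silence_epochs(tier, min_ms=100)
        assert kept.intervals == ((200, 300, "silent"),)

    def test_empty_tier_passthrough(self):
        tier = IntervalTier((), 1000)
        assert filter_silence_epochs(tier).intervals == ()

    def test_matches_brute_force_and_never_grows(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            cursor, intervals = 0, []
            while cursor < 4000 and len(intervals) < 12:
                cursor += int(rng.integers(1, 300))
                length = int(rng.integers(1, 400))
                if cursor + length > 5000:
                    break
                intervals.append((cursor, cursor + length, "silent"))
                cursor += length
            tier = IntervalTier(tuple(intervals), 5000)
            min_ms = int(rng.integers(1, 300))
            kept = filter_silence_epochs(tier, min_ms)
            expect = tuple(iv for iv in intervals if iv[1] - iv[0] >= min_ms)
            assert kept.intervals == expect
            assert kept.total_ms() <= tier.total_ms()


class TestMarkSilent:
    def test_majority_coverage_rule(self):
        timeline = FrameTimeline.from_duration_ms(100, 50)  # 20 ms windows
        half = mark_silent(IntervalTier(((10, 20, "silent"),), 100), timeline)
        assert half[0]  # exactly 50% covered -> silent
        under = mark_silent(IntervalTier(((11, 20, "silent"),), 100), timeline)
        assert not under[0]

    def test_playing_and_silent_disjoint_on_rendered_sessions(self, zero_noise_run):
        _, _, states, _ = zero_noise_run
        assert not any(s.playing and s.silent for s in states)
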