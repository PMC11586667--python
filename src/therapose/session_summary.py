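"""Session-level psychometrics: per-attribute time percentages and
cross-session comparison.

Every attribute's categories are reported as percentages of session frames.
The exhaustive categorical attributes (body pose; self-touch region
including none; playing hand; head pose; torso pose) sum to exactly 100
before rounding; playing and silence are single percentages. Self-touch
additionally reports, per region, the sub-percentage that occurred while
playing. Display follows the conventions of the published case-study
tables: session cells round to integers, averages to one decimal, and
near-boundary values print as "~0" / "~100" while exact 0 and 100 print
plainly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .behavior_classify import (
    BODY_POSES,
    HANDS,
    HEAD_POSES,
    TORSO_POSES,
    TOUCH_REGIONS,
)
from .errors import ValidationError

ATTRIBUTE_CATEGORIES = {
    "body_pose": BODY_POSES,
    "self_touch": TOUCH_REGIONS,
    "playing_hand": HANDS,
    "head_pose": HEAD_POSES,
    "torso_pose": TORSO_POSES,
}

_TOUCH_PLAYING_REGIONS = ("head_upper_torso", "middle_torso")


@dataclass(frozen=True)
class SessionSummary:
    """One session's percentage table (unrounded values)."""

    session_id: str
    n_frames: int
    fps: float
    playing_pct: float
    silence_pct: float
    body_pose: dict
    self_touch: dict
    self_touch_while_playing: dict
    playing_hand: dict
    head_pose: dict
    torso_pose: dict

    def attribute(self, name: str) -> dict:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "n_frames": self.n_frames,
            "fps": self.fps,
            "playing_pct": self.playing_pct,
            "silence_pct": self.silence_pct,
            "body_pose": dict(self.body_pose),
            "self_touch": dict(self.self_touch),
            "self_touch_while_playing": dict(self.self_touch_while_playing),
            "playing_hand": dict(self.playing_hand),
            "head_pose": dict(self.head_pose),
            "torso_pose": dict(self.torso_pose),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SessionSummary":
        return cls(**doc)

    @classmethod
    def from_percentages(
        cls,
        session_id: str,
        playing_pct: float,
        silence_pct: float,
        body_pose: dict,
        self_touch: dict,
        self_touch_while_playing: dict,
        playing_hand: dict,
        head_pose: dict,
        torso_pose: dict,
        n_frames: int = 0,
        fps: float = 50.0,
    ) -> "SessionSummary":
        """Build a summary directly from published percentage values."""
        return cls(
            session_id,
            n_frames,
            fps,
            playing_pct,
            silence_pct,
            dict(body_pose),
            dict(self_touch),
            dict(self_touch_while_playing),
            dict(playing_hand),
            dict(head_pose),
            dict(torso_pose),
        )


@dataclass(frozen=True)
class ComparisonReport:
    """Per-session values and their arithmetic mean, per attribute/category."""

    subject_id: str
    session_ids: tuple
    rows: dict  # (attribute, category) -> {"sessions": [...], "mean": float}

    def mean(self, attribute: str, category: str | None = None) -> float:
        return self.rows[(attribute, category)]["mean"]


def summarize(states, fps: float, session_id: str = "session") -> SessionSummary:
    """Aggregate frame states into the per-session percentage table."""
    states = list(states)
    if not states:
        raise ValidationError("cannot summarize an empty state sequence")
    n = len(states)

    def pct(count: int) -> float:
        return 100.0 * count / n

    categorical = {}
    for attr, cats in ATTRIBUTE_CATEGORIES.items():
        counts = {c: 0 for c in cats}
        for s in states:
            counts[getattr(s, attr if attr != "self_touch" else "self_touch")] += 1
        categorical[attr] = {c: pct(k) for c, k in counts.items()}

    touch_playing = {
        r: pct(
            sum(1 for s in states if s.self_touch == r and s.self_touch_while_playing)
        )
        for r in _TOUCH_PLAYING_REGIONS
    }
    return SessionSummary(
        session_id=session_id,
        n_frames=n,
        fps=fps,
        playing_pct=pct(sum(1 for s in states if s.playing)),
        silence_pct=pct(sum(1 for s in states if s.silent)),
        body_pose=categorical["body_pose"],
        self_touch=categorical["self_touch"],
        self_touch_while_playing=touch_playing,
        playing_hand=categorical["playing_hand"],
        head_pose=categorical["head_pose"],
        torso_pose=categorical["torso_pose"],
    )


def render_percent(value: float, mode: str = "session") -> str:
    """Format a percentage the way the session tables print them.

    Exact 0 and 100 print plainly; values in (0, 0.5) print "~0" and values
    in (99.5, 100) print "~100" (both distinct from the exact endpoints).
    Otherwise session cells round half-up to integers and average cells to
    one decimal (trailing .0 dropped).
    """
    if not 0.0 <= value <= 100.0:
        raise ValidationError(f"percentage {value} outside [0, 100]")
    if value == 0.0:
        return "0"
    if value == 100.0:
        return "100"
    if value < 0.5:
        return "∼0"
    if value > 99.5:
        return "∼100"
    if mode == "average":
        rounded = math.floor(value * 10 + 0.5) / 10
        return f"{rounded:.1f}".rstrip("0").rstrip(".")
    return str(int(math.floor(value + 0.5)))


def compare_sessions(summaries, subject_id: str = "subject") -> ComparisonReport:
    """Average unrounded per-session percentages across sessions of a subject."""
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValidationError("need at least two sessions to compare")
    attrs = [
        "body_pose",
        "self_touch",
        "self_touch_while_playing",
        "playing_hand",
        "head_pose",
        "torso_pose",
    ]
    ref = summaries[0]
    for s in summaries[1:]:
        for attr in attrs:
            if set(s.attribute(attr)) != set(ref.attribute(attr)):
                raise ValidationError(
                    f"session {s.session_id}: attribute {attr} categories differ"
                )

    rows = {}

    def add(attribute, category, values):
        rows[(attribute, category)] = {
            "sessions": list(values),
            "mean": sum(values) / len(values),
        }

    add("playing", None, [s.playing_pct for s in summaries])
    add("silence", None, [s.silence_pct for s in summaries])
    for attr in attrs:
        for category in ref.attribute(attr):
            add(attr, category, [s.attribute(attr)[category] for s in summaries])
    return ComparisonReport(
        subject_id=subject_id,
        session_ids=tuple(s.session_id for s in summaries),
        rows=rows,
    )


def comparison_table(report: ComparisonReport):
    """Comparison report as a pandas DataFrame (one row per attribute/category)."""
    import pandas as pd

    records = []
    for (attribute, category), row in report.rows.items():
        rec = {"attribute": attribute, "category": category or ""}
        for sid, value in zip(report.session_ids, row["sessions"]):
            rec[f"session_{sid}"] = value
        rec["mean"] = row["mean"]
        rec["mean_display"] = render_percent(row["mean"], "average")
        records.append(rec)
    return pd.DataFrame(records)
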