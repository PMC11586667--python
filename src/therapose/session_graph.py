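"""Graphic imaging of a session: one color-coded track per attribute.

The abscissa is the session timeline in minutes; each attribute occupies a
horizontal track whose colored segments are the label runs of the (smoothed)
state stream, with the session percentages printed in the right margin and
optional numbered event annotations. SVG is the output of record — it is
built as a plain string so identical inputs give byte-identical files and
tests can re-parse the run rectangles; PNG is a convenience raster export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .session_summary import SessionSummary, render_percent

#: Attribute -> per-frame accessor on FrameStates.
TRACK_ACCESSORS = {
    "playing": lambda s: "playing" if s.playing else "not_playing",
    "silence": lambda s: "silent" if s.silent else "sounding",
    "body_pose": lambda s: s.body_pose,
    "self_touch": lambda s: s.self_touch,
    "playing_hand": lambda s: s.playing_hand,
    "head_pose": lambda s: s.head_pose,
    "torso_pose": lambda s: s.torso_pose,
}

DEFAULT_TRACKS = (
    "playing",
    "silence",
    "body_pose",
    "self_touch",
    "playing_hand",
    "head_pose",
    "torso_pose",
)

#: Fixed category palette; anything unlisted falls back to gray.
DEFAULT_COLORS = {
    ("playing", "playing"): "#2b8cbe",
    ("playing", "not_playing"): "#ece7f2",
    ("silence", "silent"): "#fdbb84",
    ("silence", "sounding"): "#efedf5",
    ("body_pose", "sitting"): "#a6bddb",
    ("body_pose", "standing"): "#e34a33",
    ("self_touch", "none"): "#f0f0f0",
    ("self_touch", "head_upper_torso"): "#756bb1",
    ("self_touch", "middle_torso"): "#bcbddc",
    ("playing_hand", "not_playing"): "#f0f0f0",
    ("playing_hand", "both"): "#31a354",
    ("playing_hand", "left"): "#a1d99b",
    ("playing_hand", "right"): "#74c476",
    ("head_pose", "neutral"): "#f0f0f0",
    ("head_pose", "up"): "#fec44f",
    ("head_pose", "down"): "#d95f0e",
    ("torso_pose", "neutral"): "#f0f0f0",
    ("torso_pose", "open"): "#3182bd",
    ("torso_pose", "closed"): "#9ecae1",
}


@dataclass(frozen=True)
class GraphSpec:
    tracks: tuple = DEFAULT_TRACKS
    annotations: tuple = ()  # of (time_ms, label)
    width: int = 960
    track_height: int = 28
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    fmt: str = "svg"

    def __post_init__(self):
        if not self.tracks:
            raise ValidationError("GraphSpec.tracks must be non-empty")
        unknown = set(self.tracks) - set(TRACK_ACCESSORS)
        if unknown:
            raise ValidationError(f"unknown tracks {sorted(unknown)}")


def _track_runs(states, track):
    """(start_ms, end_ms, category) runs of one attribute over the session."""
    accessor = TRACK_ACCESSORS[track]
    runs = []
    start = 0
    labels = [accessor(s) for s in states]
    frame_ms = states[1].time_ms - states[0].time_ms if len(states) > 1 else 20
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            end_ms = (
                states[i].time_ms if i < len(labels) else states[-1].time_ms + frame_ms
            )
            runs.append((states[start].time_ms, end_ms, labels[start]))
            start = i
    return runs


def _percent_caption(summary: SessionSummary, track: str) -> str:
    if track == "playing":
        return f"playing {render_percent(summary.playing_pct)}"
    if track == "silence":
        return f"silent {render_percent(summary.silence_pct)}"
    table = summary.attribute(track)
    return "  ".join(f"{cat} {render_percent(v)}" for cat, v in table.items())


def render_session(states, summary: SessionSummary, spec: GraphSpec, path) -> None:
    """Write the session timeline figure to ``path`` (SVG or PNG per spec.fmt)."""
    states = list(states)
    if not states:
        raise ValidationError("no states to render")
    duration_ms = states[-1].time_ms + (
        states[1].time_ms - states[0].time_ms if len(states) > 1 else 20
    )
    for time_ms, _ in spec.annotations:
        if not 0 <= time_ms <= duration_ms:
            raise ValidationError(f"annotation at {time_ms} ms outside the session")
    if spec.fmt == "svg":
        Path(path).write_text(_render_svg(states, summary, spec, duration_ms))
    elif spec.fmt == "png":
        _render_png(states, summary, spec, duration_ms, path)
    else:
        raise ValidationError(f"unsupported figure format {spec.fmt!r}")


def _layout(spec, duration_ms):
    left, right, top = 110, 330, 30
    plot_w = spec.width - left - right
    def x(ms):
        return left + plot_w * ms / duration_ms
    return left, right, top, plot_w, x


def _render_svg(states, summary, spec, duration_ms) -> str:
    left, right, top, plot_w, x = _layout(spec, duration_ms)
    height = top + len(spec.tracks) * (spec.track_height + 8) + 40
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.width}" '
        f'height="{height}" font-family="sans-serif" font-size="11">'
    ]
    for t, track in enumerate(spec.tracks):
        y = top + t * (spec.track_height + 8)
        parts.append(
            f'<text x="{left - 8}" y="{y + spec.track_height / 2 + 4:.2f}" '
            f'text-anchor="end" class="label">{track.replace("_", " ")}</text>'
        )
        for start_ms, end_ms, cat in _track_runs(states, track):
            color = spec.colors.get((track, cat), "#bbbbbb")
            parts.append(
                f'<rect class="run track-{track} cat-{cat}" '
                f'x="{x(start_ms):.2f}" y="{y}" '
                f'width="{x(end_ms) - x(start_ms):.2f}" '
                f'height="{spec.track_height}" fill="{color}"/>'
            )
        parts.append(
            f'<text x="{left + plot_w + 8}" y="{y + spec.track_height / 2 + 4:.2f}" '
            f'class="stats">{_percent_caption(summary, track)}</text>'
        )
    # minute ticks on the shared abscissa
    axis_y = top + len(spec.tracks) * (spec.track_height + 8) + 4
    total_min = duration_ms / 60000.0
    step = max(1, int(total_min // 10) or 1)
    minute = 0
    while minute <= total_min + 1e-9:
        tick_x = x(minute * 60000)
        parts.append(
            f'<line x1="{tick_x:.2f}" y1="{axis_y}" x2="{tick_x:.2f}" '
            f'y2="{axis_y + 5}" stroke="#333"/>'
        )
        parts.append(
            f'<text x="{tick_x:.2f}" y="{axis_y + 18}" text-anchor="middle" '
            f'class="tick">{minute}</text>'
        )
        minute += step
    parts.append(
        f'<text x="{left + plot_w / 2:.2f}" y="{axis_y + 34}" '
        f'text-anchor="middle" class="axis">time (min)</text>'
    )
    for i, (time_ms, label) in enumerate(spec.annotations, start=1):
        ax = x(time_ms)
        parts.append(
            f'<g class="annotation"><circle cx="{ax:.2f}" cy="{top - 12}" r="8" '
            f'fill="none" stroke="#d7301f"/>'
            f'<text x="{ax:.2f}" y="{top - 8}" text-anchor="middle" '
            f'fill="#d7301f">({i})</text>'
            f'<title>{label}</title></g>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_png(states, summary, spec, duration_ms, path) -> None:
    from PIL import Image, ImageDraw

    left, right, top, plot_w, x = _layout(spec, duration_ms)
    height = top + len(spec.tracks) * (spec.track_height + 8) + 40
    img = Image.new("RGB", (spec.width, height), "white")
    draw = ImageDraw.Draw(img)
    for t, track in enumerate(spec.tracks):
        y = top + t * (spec.track_height + 8)
        draw.text((4, y + spec.track_height / 2 - 5), track.replace("_", " "), fill="black")
        for start_ms, end_ms, cat in _track_runs(states, track):
            color = spec.colors.get((track, cat), "#bbbbbb")
            draw.rectangle(
                [x(start_ms), y, x(end_ms), y + spec.track_height], fill=color
            )
        draw.text(
            (left + plot_w + 8, y + spec.track_height / 2 - 5),
            _percent_caption(summary, track),
            fill="black",
        )
    axis_y = top + len(spec.tracks) * (spec.track_height + 8) + 4
    draw.line([left, axis_y, left + plot_w, axis_y], fill="black")
    img.save(path, format="PNG")
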