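"""Minimal Standard MIDI File (SMF) reader and writer.

Only the subset needed for keyboard-session capture is handled: format 0/1
files, note-on/note-off channel messages, and set-tempo meta events. Running
status is supported on read. Times are converted from pulses to integer
milliseconds using the tempo map (default 120 BPM when no tempo event is
present, per the SMF specification).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from .errors import FormatError

DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 BPM)


@dataclass(frozen=True)
class RawNote:
    onset_ms: int
    offset_ms: int
    pitch: int
    velocity: int


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise FormatError("truncated variable-length quantity in MIDI track")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _track_events(data: bytes):
    """Yield (tick, status, payload) from one MTrk chunk body."""
    pos = 0
    tick = 0
    running = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running = status
        else:
            if running is None:
                raise FormatError("running status byte with no prior status")
            status = running
        if status == 0xFF:  # meta
            meta_type = data[pos]
            length, pos = _read_varlen(data, pos + 1)
            yield tick, status, bytes([meta_type]) + data[pos : pos + length]
            pos += length
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            n_data = 1 if (status & 0xF0) in (0xC0, 0xD0) else 2
            yield tick, status, data[pos : pos + n_data]
            pos += n_data


def read_smf(path) -> list[RawNote]:
    """Parse an SMF file into closed notes sorted by onset.

    Note-on with velocity 0 closes a note (the common keyboard convention);
    notes still open at end of stream are closed at the last event tick.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd" or len(data) < 14:
        raise FormatError(f"{path}: not a Standard MIDI File (missing MThd header)")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise FormatError("SMPTE time division is not supported")
    if division == 0:
        raise FormatError("zero ticks-per-quarter division")

    pos = 8 + header_len
    tracks = []
    while pos + 8 <= len(data) and len(tracks) < n_tracks:
        chunk_id = data[pos : pos + 4]
        (chunk_len,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        body = data[pos + 8 : pos + 8 + chunk_len]
        pos += 8 + chunk_len
        if chunk_id == b"MTrk":
            tracks.append(body)

    # Tempo map: (tick, us_per_qn), gathered across all tracks.
    tempi = [(0, DEFAULT_TEMPO_US)]
    events = []  # (tick, status, payload)
    for body in tracks:
        for tick, status, payload in _track_events(body):
            if status == 0xFF and payload[:1] == b"\x51":
                tempi.append((tick, int.from_bytes(payload[1:4], "big")))
            else:
                events.append((tick, status, payload))
    tempi.sort()

    def tick_to_ms(tick: int) -> int:
        us = 0.0
        prev_tick, tempo = tempi[0]
        for t_tick, t_us in tempi[1:]:
            if t_tick >= tick:
                break
            us += (t_tick - prev_tick) * tempo / division
            prev_tick, tempo = t_tick, t_us
        us += (tick - prev_tick) * tempo / division
        return round(us / 1000.0)

    events.sort(key=lambda e: e[0])
    open_notes: dict[tuple[int, int], tuple[int, int]] = {}
    notes = []
    last_tick = 0
    for tick, status, payload in events:
        last_tick = max(last_tick, tick)
        kind = status & 0xF0
        channel = status & 0x0F
        if kind == 0x90 and payload[1] > 0:  # note on
            open_notes[(channel, payload[0])] = (tick, payload[1])
        elif kind == 0x80 or (kind == 0x90 and payload[1] == 0):  # note off
            started = open_notes.pop((channel, payload[0]), None)
            if started is not None:
                on_tick, velocity = started
                notes.append(
                    RawNote(tick_to_ms(on_tick), tick_to_ms(tick), payload[0], velocity)
                )
    for (channel, pitch), (on_tick, velocity) in open_notes.items():
        off = max(tick_to_ms(last_tick), tick_to_ms(on_tick) + 1)
        notes.append(RawNote(tick_to_ms(on_tick), off, pitch, velocity))
    notes.sort(key=lambda n: (n.onset_ms, n.pitch))
    return notes


def write_smf(path, notes, ticks_per_ms: int = 1) -> None:
    """Write notes as a format-0 SMF with 1 ms tick resolution.

    Uses division = 500 ticks per quarter at 120 BPM so one tick is exactly
    one millisecond, keeping the file lossless for integer-ms note tables.
    """
    division = 500 * ticks_per_ms
    msgs = []  # (tick, sort_rank, bytes)
    for i, n in enumerate(notes):
        msgs.append((n.onset_ms * ticks_per_ms, 1, bytes([0x90, n.pitch, n.velocity])))
        msgs.append((n.offset_ms * ticks_per_ms, 0, bytes([0x80, n.pitch, 0])))
    msgs.sort(key=lambda m: (m[0], m[1]))
    body = bytearray()
    body += _write_varlen(0) + b"\xff\x51\x03" + DEFAULT_TEMPO_US.to_bytes(3, "big")
    prev = 0
    for tick, _, raw in msgs:
        body += _write_varlen(tick - prev) + raw
        prev = tick
    body += _write_varlen(0) + b"\xff\x2f\x00"
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, division))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
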