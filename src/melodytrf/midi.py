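"""Minimal standard-MIDI (SMF) reading and writing for monophonic melodies.

Supports what the analysis needs and nothing more: format-0/1 files, one
monophonic note stream, tempo maps and time signatures.  Overlapping notes
(polyphony) are rejected with the offending tick, since every analysis in
this package assumes a single melodic voice.

Onset times are derived from the tempo map (default 120 bpm when absent,
with a warning); bar indices from the time signature; inter-onset-interval
classes from a tatum grid — each IOI is expressed as its integer multiple
of the smallest note value (either supplied or estimated as the minimum
IOI in the piece).
"""

from __future__ import annotations

import struct
import warnings

import numpy as np

from .melody import INITIAL_IOI_CLASS, MelodySequence, NoteEvent

__all__ = ["write_midi", "parse_midi"]

_DEFAULT_TEMPO = 500000  # microseconds per quarter note (120 bpm)


def _encode_varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def _decode_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def write_midi(
    melody: MelodySequence,
    path,
    ppq: int = 480,
    velocity: int = 80,
) -> None:
    """Write a melody as a single-track (format 0) standard MIDI file.

    The tempo is chosen so one 4/4 bar lasts ``melody.bar_duration_s``;
    onsets and durations are quantized to the tick grid (1/``ppq`` of a
    quarter note).
    """
    quarter_s = melody.bar_duration_s / 4.0
    tempo = int(round(quarter_s * 1e6))

    def to_ticks(t: float) -> int:
        return int(round(t / quarter_s * ppq))

    events = [
        (0, bytes([0xFF, 0x58, 0x04, 4, 2, 24, 8])),  # 4/4 time signature
        (0, bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big")),
    ]
    for note in melody.notes:
        on = to_ticks(note.onset_s)
        off = max(on + 1, to_ticks(note.onset_s + note.duration_s))
        events.append((on, bytes([0x90, note.pitch & 0x7F, velocity])))
        events.append((off, bytes([0x80, note.pitch & 0x7F, 0])))
    events.sort(key=lambda e: (e[0], e[1][0] != 0x80))  # offs before ons at a tick
    track = bytearray()
    prev = 0
    for tick, msg in events:
        track += _encode_varlen(tick - prev) + msg
        prev = tick
    track += _encode_varlen(0) + bytes([0xFF, 0x2F, 0x00])  # end of track
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ppq))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


def _read_events(data: bytes):
    """Yield (tick, kind, payload) merged over all tracks."""
    if data[:4] != b"MThd":
        raise ValueError("not a standard MIDI file (missing MThd)")
    _, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division is not supported")
    pos = 14
    merged = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("malformed MIDI: expected MTrk chunk")
        length = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        body = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        tick = 0
        p = 0
        status = 0
        while p < len(body):
            delta, p = _decode_varlen(body, p)
            tick += delta
            b = body[p]
            if b & 0x80:
                status = b
                p += 1
            if status == 0xFF:
                meta = body[p]
                ln, p2 = _decode_varlen(body, p + 1)
                payload = body[p2 : p2 + ln]
                p = p2 + ln
                merged.append((tick, "meta", (meta, payload)))
            elif status in (0xF0, 0xF7):
                ln, p2 = _decode_varlen(body, p)
                p = p2 + ln
            else:
                kind = status & 0xF0
                if kind in (0xC0, 0xD0):
                    merged.append((tick, "other", body[p : p + 1]))
                    p += 1
                else:
                    d1, d2 = body[p], body[p + 1]
                    p += 2
                    if kind == 0x90 and d2 > 0:
                        merged.append((tick, "on", (d1, d2)))
                    elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                        merged.append((tick, "off", (d1, d2)))
    merged.sort(key=lambda e: (e[0], e[1] != "off"))
    return merged, division


def parse_midi(path, tatum_s: float | None = None) -> MelodySequence:
    """Parse a monophonic standard MIDI file into a :class:`MelodySequence`.

    Onsets follow the tempo map; bar indices follow the time signature and
    tempo; IOI classes are integer multiples of the tatum (the smallest
    note value — estimated from the piece unless supplied).  Two notes
    sounding at once raise a polyphony error naming the first offending
    tick.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    events, ppq = _read_events(data)

    # tick -> seconds under the tempo map
    tempo = None
    numer, denom = 4, 4
    t_s = 0.0
    last_tick = 0
    notes_raw = []  # (onset_s, pitch, offset_s placeholder)
    active: dict[int, tuple[float, int]] = {}
    order = 0
    for tick, kind, payload in events:
        cur_tempo = tempo if tempo is not None else _DEFAULT_TEMPO
        t_s += (tick - last_tick) * cur_tempo / 1e6 / ppq
        last_tick = tick
        if kind == "meta":
            meta, body = payload
            if meta == 0x51:
                tempo = int.from_bytes(body, "big")
            elif meta == 0x58 and len(body) >= 2:
                numer, denom = body[0], 2 ** body[1]
        elif kind == "on":
            if active:
                raise ValueError(
                    f"polyphony: note {payload[0]} starts at tick {tick} "
                    f"while {sorted(active)} still sounding"
                )
            active[payload[0]] = (t_s, order)
            order += 1
        elif kind == "off":
            if payload[0] in active:
                onset, idx = active.pop(payload[0])
                notes_raw.append((onset, payload[0], t_s - onset, idx))
    if tempo is None:
        warnings.warn("no tempo event; assuming 120 bpm")
        tempo = _DEFAULT_TEMPO
    if not notes_raw:
        raise ValueError("MIDI file contains no notes")
    notes_raw.sort(key=lambda r: r[3])

    onsets = np.array([r[0] for r in notes_raw])
    iois = np.diff(onsets)
    if tatum_s is None:
        tatum_s = float(iois.min()) if len(iois) else 0.25
    classes = [INITIAL_IOI_CLASS] + [int(round(i / tatum_s)) for i in iois]

    bar_s = numer * (4.0 / denom) * tempo / 1e6
    notes = [
        NoteEvent(
            onset_s=float(r[0]),
            duration_s=float(r[2]),
            pitch=int(r[1]),
            ioi_class=classes[i],
            bar_index=int(r[0] / bar_s + 1e-9),
        )
        for i, r in enumerate(notes_raw)
    ]
    return MelodySequence(notes, piece_id="midi", bar_duration_s=bar_s)
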