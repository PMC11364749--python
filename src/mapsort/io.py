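"""On-disk artifacts: pulse binary, wavelet binary, FCS 3.1 list mode.

An acquisition delivers three files: raw pulse shapes, wavelet
coefficients, and an FCS file with conventional A/H/W parameters.  The
real instrument's binary layout is proprietary, so this package defines
its own versioned layout (documented below) and keeps a narrow reader
interface that foreign-layout adapters can plug into.

Pulse binary (little-endian throughout)::

    magic    4 bytes  b"MAPP"   (b"MAPW" for the coefficient file)
    version  uint32   1
    n_channels      uint32
    n_per_event     uint32     samples (or coefficients) per channel
    sampling_rate   float64    Hz (0 for the coefficient file)
    n_events        uint64
    then per event: event_id uint64, timestamp float64,
                    data float32[n_channels × n_per_event]

FCS output is FCS 3.1 (float32 list mode, $DATATYPE/F, $BYTEORD
1,2,3,4); the reader also accepts FCS 3.0 headers.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .simulate import EventRecord

__all__ = [
    "write_pulses",
    "read_pulses",
    "iter_pulses",
    "write_coeffs",
    "read_coeffs",
    "write_fcs",
    "read_fcs",
    "FormatError",
]

_PULSE_MAGIC = b"MAPP"
_COEFF_MAGIC = b"MAPW"
_VERSION = 1
_HEADER = struct.Struct("<4sIIIdQ")
_EVENT_HEAD = struct.Struct("<Qd")


class FormatError(ValueError):
    """Malformed or truncated binary artifact (reports the byte offset)."""


def _write_records(
    path: str | Path,
    magic: bytes,
    data: np.ndarray,
    event_ids: np.ndarray,
    timestamps: np.ndarray,
    sampling_rate: float,
) -> None:
    n_events, n_channels, n_per = data.shape
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(magic, _VERSION, n_channels, n_per, sampling_rate, n_events))
        for i in range(n_events):
            fh.write(_EVENT_HEAD.pack(int(event_ids[i]), float(timestamps[i])))
            fh.write(np.ascontiguousarray(data[i], dtype="<f4").tobytes())


def _iter_records(path: str | Path, magic: bytes) -> Iterator[tuple[int, float, np.ndarray]]:
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise FormatError(f"{path}: truncated header at byte {len(head)}")
        m, version, n_channels, n_per, rate, n_events = _HEADER.unpack(head)
        if m != magic:
            raise FormatError(f"{path}: bad magic {m!r} at byte 0 (expected {magic!r})")
        if version != _VERSION:
            raise FormatError(f"{path}: unsupported version {version}")
        rec_bytes = n_channels * n_per * 4
        offset = _HEADER.size
        for i in range(n_events):
            eh = fh.read(_EVENT_HEAD.size)
            if len(eh) < _EVENT_HEAD.size:
                raise FormatError(f"{path}: truncated at byte {offset} (event {i})")
            event_id, ts = _EVENT_HEAD.unpack(eh)
            raw = fh.read(rec_bytes)
            if len(raw) < rec_bytes:
                raise FormatError(
                    f"{path}: truncated at byte {offset + _EVENT_HEAD.size} (event {i})"
                )
            data = np.frombuffer(raw, dtype="<f4").reshape(n_channels, n_per)
            yield event_id, ts, data
            offset += _EVENT_HEAD.size + rec_bytes
        if fh.read(1):
            raise FormatError(f"{path}: trailing bytes after {n_events} events")


def write_pulses(path: str | Path, events: list[EventRecord], sampling_rate: float = 10e6) -> None:
    """Write events' waveforms to the pulse binary (lossless float32)."""
    if not events:
        data = np.zeros((0, 0, 0), dtype="<f4")
        _write_records(path, _PULSE_MAGIC, data, np.zeros(0), np.zeros(0), sampling_rate)
        return
    shapes = {ev.waveforms.shape for ev in events}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous waveform shapes: {shapes}")
    data = np.stack([ev.waveforms for ev in events]).astype("<f4")
    ids = np.array([ev.event_id for ev in events])
    ts = np.array([ev.timestamp for ev in events])
    _write_records(path, _PULSE_MAGIC, data, ids, ts, sampling_rate)


def iter_pulses(path: str | Path) -> Iterator[EventRecord]:
    """Stream events from a pulse binary (constant memory per event)."""
    for event_id, ts, data in _iter_records(path, _PULSE_MAGIC):
        yield EventRecord(event_id=int(event_id), timestamp=ts, waveforms=data.copy())


def read_pulses(path: str | Path) -> list[EventRecord]:
    return list(iter_pulses(path))


def write_coeffs(
    path: str | Path,
    coeffs: np.ndarray,
    event_ids: np.ndarray | None = None,
    timestamps: np.ndarray | None = None,
) -> None:
    """Write an (n_events, n_channels, n_coeffs) coefficient array."""
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 3:
        raise ValueError("coeffs must be (n_events, n_channels, n_coeffs)")
    n = coeffs.shape[0]
    ids = np.arange(n) if event_ids is None else np.asarray(event_ids)
    ts = np.zeros(n) if timestamps is None else np.asarray(timestamps)
    _write_records(path, _COEFF_MAGIC, coeffs.astype("<f4"), ids, ts, 0.0)


def read_coeffs(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a coefficient binary: (coeffs, event_ids, timestamps)."""
    ids, ts, rows = [], [], []
    for event_id, t, data in _iter_records(path, _COEFF_MAGIC):
        ids.append(event_id)
        ts.append(t)
        rows.append(data.copy())
    if not rows:
        return np.zeros((0, 0, 0), dtype=np.float32), np.zeros(0, dtype=np.int64), np.zeros(0)
    return np.stack(rows), np.asarray(ids, dtype=np.int64), np.asarray(ts)


# --------------------------------------------------------------------------
# FCS 3.1 list mode
# --------------------------------------------------------------------------

_DELIM = "/"


def write_fcs(path: str | Path, table: pd.DataFrame, version: str = "FCS3.1") -> None:
    """Write a per-event feature table as an FCS 3.1 list-mode file.

    Columns become FCS parameters ($PnN = column name, e.g. ``ch0-A``);
    DATA is float32 little-endian list mode.  At most 99 parameters.
    """
    n_events, n_par = table.shape
    if n_par > 99:
        raise ValueError("FCS list mode supports at most 99 parameters here")
    if n_par == 0 and n_events > 0:
        raise ValueError("events without parameters")
    data = np.ascontiguousarray(table.to_numpy(dtype="<f4"))
    payload = data.tobytes()

    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(table.columns, start=1):
        if _DELIM in str(name):
            raise ValueError(f"parameter name {name!r} contains the delimiter")
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        col = table[name].to_numpy(dtype=float)
        rng = float(np.nanmax(col)) if n_events else 1.0
        kw[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    header_len = 58  # 6+4 + 4×(2×8) offsets, space padded
    # iterate: TEXT length depends on the offsets' digit count; two passes settle it
    data_start = 0
    text = b""
    for _ in range(3):
        kw["$BEGINDATA"] = str(data_start)
        kw["$ENDDATA"] = str(data_start + max(len(payload) - 1, 0) if payload else data_start)
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in sorted(kw.items())) + _DELIM
        text = body.encode("ascii")
        data_start = header_len + len(text)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_end = data_start + len(payload) - 1 if payload else 0

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # beyond header range: TEXT keywords carry the true offsets
        return s.rjust(8).encode("ascii")

    header = version.encode("ascii").ljust(10)
    header += _off(text_start) + _off(text_end)
    header += _off(data_start if payload else 0) + _off(data_end)
    header += _off(0) + _off(0)  # no ANALYSIS segment
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS 3.0/3.1 float list-mode file: (table, keywords)."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short for an FCS header")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", "replace")
    delim = text[0]
    toks = text.strip(delim).split(delim)
    kw = {toks[i].strip(): toks[i + 1] for i in range(0, len(toks) - 1, 2)}

    data_start = int(raw[26:34] or 0)
    data_end = int(raw[34:42] or 0)
    if data_start == 0 and "$BEGINDATA" in kw:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if n_tot == 0 or n_par == 0:
        return pd.DataFrame(columns=names), kw
    if kw.get("$DATATYPE") != "F":
        raise FormatError(f"{path}: only $DATATYPE/F/ supported")
    order = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if order == "1,2,3,4" else ">f4"
    payload = raw[data_start : data_end + 1]
    expected = n_tot * n_par * 4
    if len(payload) < expected:
        raise FormatError(f"{path}: DATA segment truncated at byte {data_start + len(payload)}")
    values = np.frombuffer(payload[:expected], dtype=dtype).reshape(n_tot, n_par)
    return pd.DataFrame(values, columns=names), kw
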