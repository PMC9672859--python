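"""Minimal reader/writer for PicoQuant PTU (tagged TTTR) files.

Supports the tagged header (all scalar tag types plus strings) and the
PicoHarp T3 record layout, which is sufficient to round-trip the
synthetic acquisitions this package generates and to ingest real
PicoHarp T3 streams:

* 32-bit records, little-endian: ``channel`` in bits 28-31, ``dtime``
  (TCSPC micro-time channel) in bits 16-27, ``nsync`` (macro-time sync
  counter) in bits 0-15.
* ``channel == 15`` marks special records: ``dtime == 0`` is a sync
  overflow (adds 65536 syncs), otherwise the low 4 bits of ``dtime``
  are external marker flags (line/frame markers).

Only this module ever sees raw hardware units; micro-times leave as bin
indices plus a resolution in ns, macro-times as sync counts plus the
sync period in ns.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import PtuFormatError

MAGIC = b"PQTTTR\x00\x00"
VERSION = b"00.0.1\x00\x00"

# tag type codes from the PTU specification
TY_EMPTY8 = 0xFFFF0008
TY_BOOL8 = 0x00000008
TY_INT8 = 0x10000008
TY_BITSET64 = 0x11000008
TY_COLOR8 = 0x12000008
TY_FLOAT8 = 0x20000008
TY_TDATETIME = 0x21000008
TY_FLOAT8_ARRAY = 0x2001FFFF
TY_ANSISTRING = 0x4001FFFF
TY_WIDESTRING = 0x4002FFFF
TY_BINARYBLOB = 0xFFFFFFFF

#: TTResultFormat_TTTRRecType code for PicoHarp T3
REC_PICOHARP_T3 = 0x00010303

_T3_WRAP = 65536  # nsync overflow period
_T3_MAX_DTIME = 4095  # 12-bit micro-time field


@dataclass
class PtuHeader:
    """Typed key/value tag collection from a PTU header."""

    tags: dict

    def __post_init__(self):
        missing = [k for k in ("TTResultFormat_TTTRRecType",
                               "TTResult_NumberOfRecords",
                               "MeasDesc_Resolution") if k not in self.tags]
        if missing:
            raise PtuFormatError(f"mandatory PTU tags missing: {missing}")
        if self.tags["MeasDesc_Resolution"] <= 0:
            raise PtuFormatError("MeasDesc_Resolution must be > 0")

    @property
    def record_type(self) -> int:
        return int(self.tags["TTResultFormat_TTTRRecType"])

    @property
    def n_records(self) -> int:
        return int(self.tags["TTResult_NumberOfRecords"])

    @property
    def resolution_ns(self) -> float:
        """Micro-time (TCSPC channel) resolution in ns."""
        return float(self.tags["MeasDesc_Resolution"]) * 1e9

    @property
    def sync_period_ns(self) -> Optional[float]:
        """Macro-time sync period in ns, if recorded."""
        v = self.tags.get("MeasDesc_GlobalResolution")
        return None if v is None else float(v) * 1e9


@dataclass
class EventStream:
    """Decoded TTTR events as parallel arrays.

    ``macro_time`` is the unwrapped sync counter (overflow corrected),
    ``micro_time`` the TCSPC bin index.  Marker records have
    ``marker_bits != 0`` and carry no micro-time semantics.
    """

    macro_time: np.ndarray
    micro_time: np.ndarray
    channel: np.ndarray
    marker_bits: np.ndarray

    def __post_init__(self):
        n = len(self.macro_time)
        for name in ("micro_time", "channel", "marker_bits"):
            if len(getattr(self, name)) != n:
                raise PtuFormatError("event arrays must share a length")

    def __len__(self) -> int:
        return len(self.macro_time)

    @property
    def is_photon(self) -> np.ndarray:
        return self.marker_bits == 0

    def photons(self) -> "EventStream":
        keep = self.is_photon
        return EventStream(self.macro_time[keep], self.micro_time[keep],
                           self.channel[keep], self.marker_bits[keep])


def _read_tags(fh, path):
    tags = {}
    while True:
        raw = fh.read(48)
        if len(raw) < 48:
            raise PtuFormatError(
                f"{path}: truncated tag at byte offset {fh.tell() - len(raw)}"
            )
        ident = raw[:32].split(b"\x00", 1)[0].decode("ascii", "replace")
        index, tag_type = struct.unpack("<iI", raw[32:40])
        value_bytes = raw[40:48]
        if tag_type in (TY_INT8, TY_BITSET64, TY_COLOR8):
            value = struct.unpack("<q", value_bytes)[0]
        elif tag_type == TY_BOOL8:
            value = bool(struct.unpack("<q", value_bytes)[0])
        elif tag_type in (TY_FLOAT8, TY_TDATETIME):
            value = struct.unpack("<d", value_bytes)[0]
        elif tag_type == TY_EMPTY8:
            value = None
        elif tag_type in (TY_ANSISTRING, TY_WIDESTRING, TY_BINARYBLOB,
                          TY_FLOAT8_ARRAY):
            length = struct.unpack("<q", value_bytes)[0]
            payload = fh.read(length)
            if len(payload) < length:
                raise PtuFormatError(f"{path}: truncated tag payload for {ident}")
            if tag_type == TY_ANSISTRING:
                value = payload.split(b"\x00", 1)[0].decode("ascii", "replace")
            elif tag_type == TY_WIDESTRING:
                value = payload.decode("utf-16-le", "replace").rstrip("\x00")
            else:
                value = payload
        else:
            raise PtuFormatError(
                f"{path}: unknown tag type 0x{tag_type:08X} for {ident}"
            )
        if ident == "Header_End":
            return tags
        key = ident if index < 0 else f"{ident}({index})"
        tags[key] = value


def read_ptu(path) -> tuple:
    """Read a PTU file; returns ``(PtuHeader, EventStream)``.

    Raises :class:`PtuFormatError` on a bad magic string, an
    unsupported record type, or a truncated file.
    """
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != MAGIC:
            raise PtuFormatError(f"{path}: not a PTU file (magic {magic!r})")
        fh.read(8)  # format version, unused
        header = PtuHeader(tags=_read_tags(fh, path))
        if header.record_type != REC_PICOHARP_T3:
            raise PtuFormatError(
                f"{path}: unsupported TTTR record type "
                f"0x{header.record_type:08X} (PicoHarp T3 only)"
            )
        payload = fh.read(4 * header.n_records)
        if len(payload) < 4 * header.n_records:
            raise PtuFormatError(
                f"{path}: record section truncated at byte offset "
                f"{fh.tell()} ({len(payload) // 4} of {header.n_records} records)"
            )
    records = np.frombuffer(payload, dtype="<u4")
    return header, _decode_picoharp_t3(records)


def _decode_picoharp_t3(records: np.ndarray) -> EventStream:
    channel = (records >> 28) & 0xF
    dtime = (records >> 16) & 0xFFF
    nsync = records & 0xFFFF
    special = channel == 15
    overflow = special & (dtime == 0)
    # each overflow record advances the sync counter epoch by 65536
    epoch = np.cumsum(overflow).astype(np.int64) * _T3_WRAP
    keep = ~overflow
    macro = nsync.astype(np.int64) + epoch
    marker = np.where(special & ~overflow, dtime & 0xF, 0)
    return EventStream(
        macro_time=macro[keep],
        micro_time=np.where(special, 0, dtime)[keep].astype(np.int64),
        channel=np.where(special, 0, channel)[keep].astype(np.int64),
        marker_bits=marker[keep].astype(np.int64),
    )


def _encode_tag(ident: str, value, tag_type: int) -> bytes:
    name = ident.encode("ascii").ljust(32, b"\x00")
    head = name + struct.pack("<i", -1)
    if tag_type == TY_EMPTY8:
        return head + struct.pack("<Iq", tag_type, 0)
    if tag_type in (TY_INT8, TY_BITSET64):
        return head + struct.pack("<Iq", tag_type, int(value))
    if tag_type == TY_FLOAT8:
        return head + struct.pack("<Id", tag_type, float(value))
    if tag_type == TY_ANSISTRING:
        payload = value.encode("ascii") + b"\x00"
        pad = (-len(payload)) % 8
        payload += b"\x00" * pad
        return head + struct.pack("<Iq", tag_type, len(payload)) + payload
    raise PtuFormatError(f"cannot encode tag type 0x{tag_type:08X}")


def write_ptu(path, events: EventStream, resolution_ns: float,
              sync_period_ns: float, extra_tags: Optional[dict] = None) -> None:
    """Write a minimal PicoHarp T3 PTU readable by :func:`read_ptu`.

    Events must be sorted by macro time; overflow records are inserted
    as needed.  Raises if a micro-time exceeds the 12-bit field.
    """
    macro = np.asarray(events.macro_time, dtype=np.int64)
    micro = np.asarray(events.micro_time, dtype=np.int64)
    channel = np.asarray(events.channel, dtype=np.int64)
    marker = np.asarray(events.marker_bits, dtype=np.int64)
    if np.any(np.diff(macro) < 0):
        raise PtuFormatError("events must be sorted by macro time")
    if np.any((micro < 0) | (micro > _T3_MAX_DTIME)):
        raise PtuFormatError(
            f"micro_time exceeds the {_T3_MAX_DTIME} limit of the 12-bit "
            "PicoHarp T3 field"
        )
    if np.any((channel < 0) | (channel > 14)):
        raise PtuFormatError("channel must be in 0..14 for PicoHarp T3")
    if np.any((marker < 0) | (marker > 15)):
        raise PtuFormatError("marker_bits must fit in 4 bits")

    epoch = macro // _T3_WRAP
    nsync = macro % _T3_WRAP
    n = len(macro)
    n_overflow = int(epoch[-1]) if n else 0
    records = np.empty(n + n_overflow, dtype="<u4")
    # interleave overflow records before the events of each new epoch
    overflow_word = np.uint32((15 << 28) | (0 << 16))
    pos = 0
    prev_epoch = 0
    out_idx = 0
    for i in range(n):
        while prev_epoch < epoch[i]:
            records[out_idx] = overflow_word
            out_idx += 1
            prev_epoch += 1
        if marker[i]:
            word = (15 << 28) | (int(marker[i]) << 16) | int(nsync[i])
        else:
            word = (int(channel[i]) << 28) | (int(micro[i]) << 16) | int(nsync[i])
        records[out_idx] = word
        out_idx += 1
    records = records[:out_idx]

    tags = {
        "File_GUID": ("{00000000-0000-0000-0000-000000000000}", TY_ANSISTRING),
        "Measurement_Mode": (3, TY_INT8),
        "MeasDesc_Resolution": (resolution_ns * 1e-9, TY_FLOAT8),
        "MeasDesc_GlobalResolution": (sync_period_ns * 1e-9, TY_FLOAT8),
        "TTResultFormat_TTTRRecType": (REC_PICOHARP_T3, TY_INT8),
        "TTResult_NumberOfRecords": (len(records), TY_INT8),
    }
    for key, value in (extra_tags or {}).items():
        tag_type = (TY_FLOAT8 if isinstance(value, float)
                    else TY_ANSISTRING if isinstance(value, str) else TY_INT8)
        tags[key] = (value, tag_type)

    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(VERSION)
        for ident, (value, tag_type) in tags.items():
            fh.write(_encode_tag(ident, value, tag_type))
        fh.write(_encode_tag("Header_End", None, TY_EMPTY8))
        fh.write(records.tobytes())
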