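"""Binary frame protocol for the JY61 family of serial IMU modules.

Each sensor sample is transmitted as three sequential 11-byte frames —
acceleration, angular velocity, attitude angle — with the layout

    0x55 | type | 8 payload bytes | checksum

where ``type`` is 0x51/0x52/0x53 respectively, the payload carries four
little-endian signed shorts (x, y, z, temperature), and the checksum is
the low byte of the sum of all preceding bytes. Raw shorts map to
physical units by the full-range convention

    accel:  raw / 32768 * 16      [g]
    gyro:   raw / 32768 * 2000    [°/s]
    angle:  raw / 32768 * 180     [°]
    temp:   raw / 100             [°C]

The module's datasheet also quotes sensitivities of 16,384 LSB/g and
131 LSB/(°/s); those are inconsistent with the stated ±16 g and
±2000 °/s ranges on a 16-bit word, so this codec follows the range-based
convention above and exposes the sensitivity-derived resolutions only
through :func:`sensitivity_resolution` for documentation purposes.

Ten consecutive sample triples are aggregated into one transmission
packet, reducing the packet rate tenfold (100 Hz sampling → 10 packets/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEADER = 0x55
TYPE_ACCEL = 0x51
TYPE_GYRO = 0x52
TYPE_ANGLE = 0x53

FRAME_BYTES = 11            # header + type + 8 payload + checksum
TRIPLE_BYTES = 3 * FRAME_BYTES

ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0
ANGLE_RANGE_DEG = 180.0
_RANGES = {"accel": ACCEL_RANGE_G, "gyro": GYRO_RANGE_DPS, "angle": ANGLE_RANGE_DEG}

#: datasheet sensitivities (LSB per physical unit); documentation only,
#: not used by the codec (see module docstring)
SENSITIVITY = {"accel": 16384.0, "gyro": 131.0}

PACKET_SIZE = 10

CSV_COLUMNS = ["index", "ax", "ay", "az", "gx", "gy", "gz", "roll", "pitch", "yaw", "temp"]


def decode_int16(low: int, high: int) -> int:
    """Combine (low, high) bytes into a two's-complement 16-bit integer."""
    if not (0 <= low <= 0xFF and 0 <= high <= 0xFF):
        raise ValueError(f"bytes must be in [0, 255], got ({low}, {high})")
    value = (high << 8) | low
    return value - 0x10000 if value >= 0x8000 else value


def encode_int16(value: int) -> tuple[int, int]:
    """Split a signed 16-bit integer into (low, high) bytes."""
    if not (-32768 <= value <= 32767):
        raise ValueError(f"value {value} outside int16 range")
    u = value & 0xFFFF
    return u & 0xFF, (u >> 8) & 0xFF


def raw_to_physical(raw, channel_kind: str):
    """Scale a raw signed short to physical units for the given channel."""
    if channel_kind not in _RANGES:
        raise ValueError(f"unknown channel kind {channel_kind!r}")
    raw = np.asarray(raw)
    if np.any(raw < -32768) or np.any(raw > 32767):
        raise ValueError("raw value outside int16 range")
    out = raw / 32768.0 * _RANGES[channel_kind]
    return float(out) if out.ndim == 0 else out


def physical_to_raw(value, channel_kind: str):
    """Inverse of :func:`raw_to_physical`, rounding to the nearest LSB."""
    if channel_kind not in _RANGES:
        raise ValueError(f"unknown channel kind {channel_kind!r}")
    rng = _RANGES[channel_kind]
    value = np.asarray(value, dtype=float)
    if np.any(np.abs(value) > rng):
        raise ValueError(f"{channel_kind} value outside ±{rng}")
    raw = np.rint(value / rng * 32768.0).astype(np.int64)
    raw = np.clip(raw, -32768, 32767)
    return int(raw) if raw.ndim == 0 else raw


def range_lsb(channel_kind: str) -> float:
    """Physical step of one LSB under the range-based scaling."""
    return _RANGES[channel_kind] / 32768.0


def sensitivity_resolution(channel_kind: str) -> float:
    """Resolution implied by the datasheet sensitivity (1/sensitivity).

    Yields 1/16384 ≈ 6.1e-5 g for acceleration and 1/131 ≈ 7.6e-3 °/s for
    angular velocity — the printed datasheet resolutions. These disagree
    with the range-based LSB actually used on the wire; see module docs.
    """
    return 1.0 / SENSITIVITY[channel_kind]


@dataclass
class FrameTriple:
    """One decoded sample: acceleration (g), gyro (°/s), angle (°), temp (°C)."""

    index: int
    accel: np.ndarray
    gyro: np.ndarray
    angle: np.ndarray
    temperature: float | None = None

    def __post_init__(self):
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.index < 0:
            raise ValueError("index must be non-negative")
        for name, vec, rng in (("accel", self.accel, ACCEL_RANGE_G),
                               ("gyro", self.gyro, GYRO_RANGE_DPS),
                               ("angle", self.angle, ANGLE_RANGE_DEG)):
            if vec.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if np.any(np.abs(vec) > rng):
                raise ValueError(f"{name} outside ±{rng}")


@dataclass
class StreamDiagnostics:
    frames_ok: int = 0
    checksum_failures: int = 0
    bytes_skipped: int = 0
    incomplete_triples: int = 0
    unknown_types: int = 0


@dataclass
class AggregatedPacket:
    """Exactly 10 consecutive frames bundled for transmission."""

    frames: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) != PACKET_SIZE:
            raise ValueError(f"packet must hold exactly {PACKET_SIZE} frames")
        idx = [f.index for f in self.frames]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must increase by exactly 1")


def pack_frames(frames) -> AggregatedPacket:
    return AggregatedPacket(frames=list(frames))


def unpack_packet(packet: AggregatedPacket) -> list:
    return list(packet.frames)


def packet_rate(frame_rate_hz: float) -> float:
    """Transmission rate after 10-frame aggregation."""
    return frame_rate_hz / PACKET_SIZE


def _checksum(body: bytes) -> int:
    return sum(body) & 0xFF


def _encode_one_frame(frame_type: int, shorts: tuple[int, int, int, int]) -> bytes:
    body = bytearray([HEADER, frame_type])
    for s in shorts:
        low, high = encode_int16(s)
        body += bytes([low, high])
    body.append(_checksum(body))
    return bytes(body)


def encode_frame(triple: FrameTriple) -> bytes:
    """Serialize one sample as its three 11-byte frames."""
    temp_raw = int(round((triple.temperature or 0.0) * 100.0))
    temp_raw = max(-32768, min(32767, temp_raw))
    acc = tuple(physical_to_raw(v, "accel") for v in triple.accel) + (temp_raw,)
    gyr = tuple(physical_to_raw(v, "gyro") for v in triple.gyro) + (temp_raw,)
    ang = tuple(physical_to_raw(v, "angle") for v in triple.angle) + (temp_raw,)
    return (_encode_one_frame(TYPE_ACCEL, acc)
            + _encode_one_frame(TYPE_GYRO, gyr)
            + _encode_one_frame(TYPE_ANGLE, ang))


def encode_stream(triples) -> bytes:
    return b"".join(encode_frame(t) for t in triples)


def _decode_payload(payload: bytes) -> tuple[int, int, int, int]:
    return tuple(decode_int16(payload[i], payload[i + 1]) for i in range(0, 8, 2))


def parse_stream(data: bytes, verify_checksum: bool = True
                 ) -> tuple[list[FrameTriple], StreamDiagnostics]:
    """Decode every complete, checksum-valid (accel, gyro, angle) triple.

    Corruption never raises: the scanner resynchronizes on the next header
    byte and reports drop counts in the diagnostics. With
    ``verify_checksum=False`` frames with bad checksums are kept.
    """
    diag = StreamDiagnostics()
    frames: list[tuple[int, tuple]] = []   # (type, shorts)
    pos = 0
    n = len(data)
    while pos < n:
        if data[pos] != HEADER:
            diag.bytes_skipped += 1
            pos += 1
            continue
        if pos + FRAME_BYTES > n:
            diag.bytes_skipped += n - pos
            break
        chunk = data[pos:pos + FRAME_BYTES]
        ftype = chunk[1]
        if ftype not in (TYPE_ACCEL, TYPE_GYRO, TYPE_ANGLE):
            diag.unknown_types += 1
            diag.bytes_skipped += 1
            pos += 1
            continue
        if _checksum(chunk[:-1]) != chunk[-1]:
            diag.checksum_failures += 1
            if verify_checksum:
                pos += 1      # resync: scan forward from the next byte
                continue
        frames.append((ftype, _decode_payload(chunk[2:10])))
        diag.frames_ok += 1
        pos += FRAME_BYTES

    triples: list[FrameTriple] = []
    i = 0
    while i < len(frames):
        if (i + 2 < len(frames)
                and frames[i][0] == TYPE_ACCEL
                and frames[i + 1][0] == TYPE_GYRO
                and frames[i + 2][0] == TYPE_ANGLE):
            acc, gyr, ang = frames[i][1], frames[i + 1][1], frames[i + 2][1]
            triples.append(FrameTriple(
                index=len(triples),
                accel=[raw_to_physical(v, "accel") for v in acc[:3]],
                gyro=[raw_to_physical(v, "gyro") for v in gyr[:3]],
                angle=[raw_to_physical(v, "angle") for v in ang[:3]],
                temperature=acc[3] / 100.0,
            ))
            i += 3
        else:
            diag.incomplete_triples += 1
            i += 1
    return triples, diag


def frames_to_table(frames) -> pd.DataFrame:
    """One row per sample with the fixed CSV column order."""
    rows = [{
        "index": f.index,
        "ax": f.accel[0], "ay": f.accel[1], "az": f.accel[2],
        "gx": f.gyro[0], "gy": f.gyro[1], "gz": f.gyro[2],
        "roll": f.angle[0], "pitch": f.angle[1], "yaw": f.angle[2],
        "temp": f.temperature if f.temperature is not None else 0.0,
    } for f in frames]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_csv(frames, path_or_buf) -> None:
    frames_to_table(frames).to_csv(path_or_buf, index=False, float_format="%.8f")


def read_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing expected columns: {missing}")
    return df[CSV_COLUMNS]


def table_to_frames(df: pd.DataFrame) -> list[FrameTriple]:
    return [FrameTriple(index=int(r["index"]),
                        accel=[r["ax"], r["ay"], r["az"]],
                        gyro=[r["gx"], r["gy"], r["gz"]],
                        angle=[r["roll"], r["pitch"], r["yaw"]],
                        temperature=float(r["temp"]))
            for r in df.to_dict("records")]
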