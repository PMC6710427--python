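"""Minimal uncompressed RGB24 AVI (RIFF) writer and reader.

Implements the plain 'DIB ' AVI layout: a RIFF('AVI ') container with an
avih/strh/strf header, one '00db' chunk per frame (bottom-up BGR rows, each
padded to a 4-byte boundary) and an idx1 index.  Lossless by construction,
which is what sub-pixel geometry tests need; any mainstream video tool can
open the files.  Only this one layout is supported on read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi", "AviError", "AviData"]


class AviError(ValueError):
    """Raised when a file is not a decodable uncompressed AVI."""


@dataclass
class AviData:
    frames: np.ndarray  # (n, h, w, 3) uint8, RGB
    fps: float


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def _frame_payload(frame: np.ndarray) -> bytes:
    """Bottom-up BGR rows, 4-byte aligned, as a DIB expects."""
    h, w, _ = frame.shape
    bgr = frame[::-1, :, ::-1]  # flip rows, swap channels
    row_bytes = w * 3
    pad = (-row_bytes) % 4
    if pad:
        padded = np.zeros((h, row_bytes + pad), dtype=np.uint8)
        padded[:, :row_bytes] = bgr.reshape(h, row_bytes)
        return padded.tobytes()
    return bgr.tobytes()


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (n, h, w, 3) uint8 RGB to ``path`` at ``fps``."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise AviError("frames must be a (n, h, w, 3) uint8 array")
    n, h, w, _ = frames.shape
    if n < 1:
        raise AviError("cannot write a zero-frame video")
    scale = 1000
    rate = round(fps * scale)
    if rate <= 0:
        raise AviError("fps must be positive")

    payloads = [_frame_payload(f) for f in frames]
    frame_size = len(payloads[0])

    avih = struct.pack(
        "<14I",
        round(1e6 * scale / rate),  # dwMicroSecPerFrame
        frame_size * round(rate / scale),  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        0x10,  # AVIF_HASINDEX
        n, 0, 1, frame_size, w, h, 0, 0, 0, 0,
    )
    strh = (
        b"vids" + b"DIB "
        + struct.pack("<IHHIIIIIIII4h", 0, 0, 0, 0, scale, rate, 0, n,
                      frame_size, 0xFFFFFFFF, 0, 0, 0, w, h)
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_size, 0, 0, 0, 0)

    hdrl = _list(b"hdrl", _chunk(b"avih", avih)
                 + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)))

    movi_payload = b"movi"
    idx_entries = []
    for p in payloads:
        # idx1 offsets are relative to the 'movi' fourcc position
        idx_entries.append(struct.pack("<4sIII", b"00db", 0x10, len(movi_payload), len(p)))
        movi_payload += _chunk(b"00db", p)
    movi = _chunk(b"LIST", movi_payload)
    idx1 = _chunk(b"idx1", b"".join(idx_entries))

    riff_payload = b"AVI " + hdrl + movi + idx1
    Path(path).write_bytes(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> AviData:
    """Read an uncompressed RGB24 AVI written by :func:`write_avi` (or any
    tool emitting the plain DIB layout)."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise AviError(f"not a RIFF/AVI file: {path}")

    width = height = None
    rate = scale = None
    bitcount = compression = None
    raw_frames: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, rate, scale, bitcount, compression
        for fourcc, body, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(body + 4, body + size)
            elif fourcc == b"strh" and buf[body:body + 4] == b"vids":
                scale, rate = struct.unpack_from("<II", buf, body + 20)
            elif fourcc == b"strf":
                (_, width, height, _, bitcount, compression) = struct.unpack_from(
                    "<IiiHHI", buf, body)
            elif fourcc in (b"00db", b"00dc"):
                raw_frames.append(buf[body:body + size])

    walk(12, len(buf))

    if width is None or not raw_frames:
        raise AviError(f"no video frames found in {path}")
    if compression != 0 or bitcount != 24:
        raise AviError(
            f"unsupported AVI codec in {path}: only uncompressed 24-bit DIB is readable")
    if not rate or not scale:
        raise AviError(f"missing frame-rate header in {path}")

    h, w = abs(height), width
    row_bytes = w * 3
    stride = row_bytes + ((-row_bytes) % 4)
    frames = np.empty((len(raw_frames), h, w, 3), dtype=np.uint8)
    for i, raw in enumerate(raw_frames):
        if len(raw) < stride * h:
            raise AviError(f"truncated frame {i} in {path}")
        rows = np.frombuffer(raw[: stride * h], dtype=np.uint8).reshape(h, stride)
        bgr = rows[:, :row_bytes].reshape(h, w, 3)
        if height > 0:  # bottom-up storage
            bgr = bgr[::-1]
        frames[i] = bgr[:, :, ::-1]
    return AviData(frames=frames, fps=rate / scale)
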