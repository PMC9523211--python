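"""Minimal uncompressed AVI (RIFF / BI_RGB) reader and writer.

Cine loops exported from ultrasound scanners are plain AVI/MP4 containers.
This module implements the small uncompressed subset of AVI (24-bit BI_RGB
'DIB ' frames, bottom-up row order) that is sufficient for lossless round
trips of grayscale cine stacks and overlay renderings, with no external
codec dependency.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi", "AviFormatError"]


class AviFormatError(ValueError):
    """Raised when a file is not an AVI this reader understands."""


def _pad_row_bytes(width: int) -> int:
    # BMP/DIB rows are padded to 4-byte boundaries
    return (width * 3 + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, frame_rate: float) -> None:
    """Write an uncompressed 24-bit AVI.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W) or (T, H, W, 3), dtype uint8
        Grayscale frames are replicated into the three BGR channels.
    frame_rate : float
        Stored as a rational rate/scale with millisecond resolution.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must have shape (T, H, W) or (T, H, W, 3)")
    if frames.dtype != np.uint8:
        raise ValueError("frames must be uint8")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")

    n, height, width = frames.shape[:3]
    rate = max(1, round(frame_rate * 1000))
    scale = 1000
    row_bytes = _pad_row_bytes(width)
    frame_bytes = row_bytes * height

    # frame payload: bottom-up BGR with per-row padding
    pad = row_bytes - width * 3
    chunks = []
    for f in frames:
        bgr = f[::-1, :, ::-1]  # bottom-up, RGB -> BGR
        if pad:
            rows = np.zeros((height, row_bytes), dtype=np.uint8)
            rows[:, : width * 3] = bgr.reshape(height, width * 3)
            payload = rows.tobytes()
        else:
            payload = bgr.tobytes()
        chunks.append(payload)

    def chunk(fourcc: bytes, data: bytes) -> bytes:
        out = fourcc + struct.pack("<I", len(data)) + data
        if len(data) % 2:
            out += b"\x00"
        return out

    def list_chunk(fourcc: bytes, data: bytes) -> bytes:
        return chunk(b"LIST", fourcc + data)

    avih = struct.pack(
        "<14I",
        int(round(1e6 * scale / rate)),  # microseconds per frame
        frame_bytes * rate // scale,  # max bytes per second
        0,  # padding granularity
        0x10,  # AVIF_HASINDEX
        n,  # total frames
        0,  # initial frames
        1,  # streams
        frame_bytes,  # suggested buffer size
        width,
        height,
        0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHH8IHHHH",
        b"vids", b"DIB ",
        0, 0, 0,  # flags, priority, language
        0, scale, rate,  # initial frames, scale, rate
        0, n, frame_bytes, 0xFFFFFFFF, 0,  # start, length, bufsize, quality, samplesize
        0, 0, width, height,  # rcFrame
    )
    strf = struct.pack(
        "<IiiHHIIiiII",
        40, width, height, 1, 24, 0, frame_bytes, 0, 0, 0, 0,
    )
    hdrl = list_chunk(
        b"hdrl",
        chunk(b"avih", avih) + list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)),
    )

    movi_payload = b"".join(chunk(b"00db", c) for c in chunks)
    movi = list_chunk(b"movi", movi_payload)

    # idx1: offsets relative to the 'movi' fourcc position
    idx_entries = []
    offset = 4
    for c in chunks:
        idx_entries.append(struct.pack("<4sIII", b"00db", 0x10, offset, len(c)))
        offset += 8 + len(c) + (len(c) % 2)
    idx1 = chunk(b"idx1", b"".join(idx_entries))

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 24-bit AVI written by :func:`write_avi`.

    Returns
    -------
    frames : ndarray, shape (T, H, W, 3), dtype uint8, RGB order
    frame_rate : float
    """
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise AviFormatError(f"{path}: not a RIFF/AVI file")

    width = height = None
    bitcount = None
    compression = None
    frame_rate = None
    payloads: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, compression, frame_rate
        for fourcc, dstart, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(dstart + 4, dstart + size)
            elif fourcc == b"strh" and size >= 40:
                fcc_type = buf[dstart : dstart + 4]
                if fcc_type == b"vids":
                    scale, rate = struct.unpack_from("<II", buf, dstart + 20)
                    if scale > 0 and rate > 0:
                        frame_rate = rate / scale
            elif fourcc == b"strf" and size >= 40 and width is None:
                _, w, h, _, bc, comp = struct.unpack_from("<IiiHHI", buf, dstart)
                width, height, bitcount, compression = w, abs(h), bc, comp
            elif fourcc in (b"00db", b"00dc") and size > 0:
                payloads.append(buf[dstart : dstart + size])

    walk(12, len(buf))

    if width is None or not payloads:
        raise AviFormatError(f"{path}: no decodable video stream found")
    if compression != 0 or bitcount != 24:
        raise AviFormatError(
            f"{path}: only uncompressed 24-bit AVI is supported "
            f"(got biCompression={compression}, biBitCount={bitcount})"
        )

    row_bytes = _pad_row_bytes(width)
    frames = np.empty((len(payloads), height, width, 3), dtype=np.uint8)
    for i, payload in enumerate(payloads):
        if len(payload) < row_bytes * height:
            raise AviFormatError(f"{path}: truncated frame {i}")
        rows = np.frombuffer(payload[: row_bytes * height], dtype=np.uint8)
        rows = rows.reshape(height, row_bytes)[:, : width * 3]
        frames[i] = rows.reshape(height, width, 3)[::-1, :, ::-1]  # bottom-up BGR -> RGB
    if frame_rate is None:
        frame_rate = 25.0
    return frames, float(frame_rate)
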