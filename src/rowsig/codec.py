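"""Lossless signal and record compression.

Signal compression is a two-stage pipeline modelled on the VBZ family used
across the nanopore ecosystem:

1. **zigzag-delta transform.** Successive differences of the signed 16-bit
   samples are taken with 16-bit wraparound arithmetic (so every delta itself
   fits in 16 bits and the transform is exactly invertible), then mapped to
   non-negative integers by the zigzag map ``z = (d << 1) XOR (d >> 15)``.
   The first value is treated as a delta from zero and stored as its own
   zigzag, keeping a single code path.

2. **Stream-variable-byte packing** in two variants:

   * ``svb32-zd`` — up to 4 bytes per value, 2 control bits per value,
     4 values per control byte (the classic StreamVByte layout);
   * ``svb16-zd`` — up to 2 bytes per value, 1 control bit per value,
     8 values per control byte (the compact layout sufficient for 16-bit
     zigzag values).

   A payload is: an unsigned 64-bit little-endian sample count, the control
   bytes (final group padded with zero bits), then the data bytes, each value
   stored little-endian in the minimal number of bytes its control code
   declares (value 0 still occupies 1 byte).

The implementation is scalar/NumPy-vectorised; equivalence, not SIMD speed,
is the contract. Record-level (whole-blob) compression supports ``zlib`` and
``zstd`` (via pyarrow), with ``none`` as identity.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass

import numpy as np

from .errors import (
    CodecRangeError,
    CodecUnavailableError,
    MalformedPayloadError,
)


@dataclass(frozen=True)
class CodecVariant:
    name: str
    max_bytes_per_value: int
    values_per_control_byte: int
    control_bits_per_value: int


SVB32 = CodecVariant("svb32-zd", 4, 4, 2)
SVB16 = CodecVariant("svb16-zd", 2, 8, 1)
VARIANTS = {v.name: v for v in (SVB32, SVB16)}

_COUNT = struct.Struct("<Q")


def zigzag_delta(signal) -> np.ndarray:
    """Forward transform: wraparound deltas then zigzag, as uint32."""
    s = np.asarray(signal, dtype=np.int16)
    if s.size == 0:
        return np.zeros(0, dtype=np.uint32)
    d = np.empty(s.size, dtype=np.int16)
    d[0] = s[0]
    np.subtract(s[1:], s[:-1], out=d[1:])  # int16 wraparound
    di = d.astype(np.int32)
    return ((di << 1) ^ (di >> 15)).astype(np.uint32)


def inverse_zigzag_delta(values) -> np.ndarray:
    """Exact inverse of :func:`zigzag_delta`, back to int16 samples."""
    z = np.asarray(values, dtype=np.uint32)
    if z.size == 0:
        return np.zeros(0, dtype=np.int16)
    if int(z.max(initial=0)) > 0xFFFF:
        raise MalformedPayloadError("zigzag value exceeds 16-bit range")
    zi = z.astype(np.int32)
    d = ((zi >> 1) ^ -(zi & 1)).astype(np.int16)
    return np.cumsum(d, dtype=np.int16)


def _value_lengths(v: np.ndarray, variant: CodecVariant) -> np.ndarray:
    lens = np.ones(v.size, dtype=np.uint8)
    lens += (v > 0xFF).astype(np.uint8)
    if variant.max_bytes_per_value == 4:
        lens += (v > 0xFFFF).astype(np.uint8)
        lens += (v > 0xFFFFFF).astype(np.uint8)
    return lens


def svb_encode(values, variant: CodecVariant) -> bytes:
    """Pack non-negative integers into a stream-variable-byte payload."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    v = np.ascontiguousarray(values, dtype=np.uint64)
    limit = 1 << (8 * variant.max_bytes_per_value)
    if v.size and int(v.max()) >= limit:
        raise CodecRangeError(
            f"value {int(v.max())} does not fit {variant.max_bytes_per_value} "
            f"bytes ({variant.name})"
        )
    n = v.size
    out = [_COUNT.pack(n)]
    if n == 0:
        return b"".join(out)
    v32 = v.astype(np.uint32)
    lens = _value_lengths(v32, variant)
    codes = lens - 1
    if variant.control_bits_per_value == 1:
        control = np.packbits(codes.astype(bool), bitorder="little")
    else:
        g = variant.values_per_control_byte
        pad = (-n) % g
        padded = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
        quads = padded.reshape(-1, g)
        control = (
            quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
        ).astype(np.uint8)
    out.append(control.tobytes())

    total = int(lens.sum(dtype=np.int64))
    data = np.zeros(total, dtype=np.uint8)
    pos = np.cumsum(lens, dtype=np.int64) - lens
    data[pos] = v32 & 0xFF
    for byte_i in range(1, variant.max_bytes_per_value):
        m = lens > byte_i
        if not m.any():
            break
        data[pos[m] + byte_i] = (v32[m] >> (8 * byte_i)) & 0xFF
    out.append(data.tobytes())
    return b"".join(out)


def svb_decode(payload: bytes, variant: CodecVariant) -> np.ndarray:
    """Exact inverse of :func:`svb_encode`; returns uint32 values."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if len(payload) < _COUNT.size:
        raise MalformedPayloadError("payload shorter than its count header")
    (n,) = _COUNT.unpack_from(payload, 0)
    g = variant.values_per_control_byte
    n_control = (n + g - 1) // g
    ctrl_end = _COUNT.size + n_control
    if len(payload) < ctrl_end:
        raise MalformedPayloadError("payload truncated in control bytes")
    if n == 0:
        if len(payload) != _COUNT.size:
            raise MalformedPayloadError("trailing bytes after empty payload")
        return np.zeros(0, dtype=np.uint32)
    control = np.frombuffer(payload, dtype=np.uint8, count=n_control,
                            offset=_COUNT.size)
    if variant.control_bits_per_value == 1:
        codes = np.unpackbits(control, bitorder="little")[:n]
    else:
        codes = np.empty(n_control * g, dtype=np.uint8)
        for j in range(g):
            codes[j::g] = (control >> (2 * j)) & 0b11
        codes = codes[:n]
    lens = codes.astype(np.int64) + 1
    total = int(lens.sum())
    if len(payload) - ctrl_end < total:
        raise MalformedPayloadError("payload truncated in data bytes")
    if len(payload) - ctrl_end > total:
        raise MalformedPayloadError("trailing bytes after payload")
    data = np.frombuffer(payload, dtype=np.uint8, count=total, offset=ctrl_end)
    pos = np.cumsum(lens) - lens
    v = data[pos].astype(np.uint32)
    for byte_i in range(1, variant.max_bytes_per_value):
        m = lens > byte_i
        if not m.any():
            break
        v[m] |= data[pos[m] + byte_i].astype(np.uint32) << (8 * byte_i)
    return v


def compress_signal(signal, codec: str) -> bytes:
    """Apply the full signal pipeline for the named codec."""
    s = np.ascontiguousarray(signal, dtype=np.int16)
    if codec == "none":
        return s.astype("<i2").tobytes()
    if codec in VARIANTS:
        return svb_encode(zigzag_delta(s), VARIANTS[codec])
    raise CodecUnavailableError(f"unknown signal codec {codec!r}")


def decompress_signal(payload: bytes, codec: str) -> np.ndarray:
    if codec == "none":
        if len(payload) % 2:
            raise MalformedPayloadError("raw int16 payload has odd length")
        return np.frombuffer(payload, dtype="<i2").astype(np.int16)
    if codec in VARIANTS:
        return inverse_zigzag_delta(svb_decode(payload, VARIANTS[codec]))
    raise CodecUnavailableError(f"unknown signal codec {codec!r}")


def _zstd():
    try:
        import pyarrow
    except ImportError as e:  # pragma: no cover - pyarrow is a hard dep
        raise CodecUnavailableError("zstd codec unavailable: pyarrow missing") from e
    return pyarrow


def record_compress(blob: bytes, codec: str) -> bytes:
    """Whole-blob compression; ``none`` is identity.

    The zstd container is prefixed with the uncompressed length (u64 LE) so
    each record stays independently decompressible.
    """
    if codec == "none":
        return bytes(blob)
    if codec == "zlib":
        return zlib.compress(bytes(blob), 6)
    if codec == "zstd":
        pa = _zstd()
        return _COUNT.pack(len(blob)) + pa.compress(bytes(blob), codec="zstd",
                                                    asbytes=True)
    raise CodecUnavailableError(f"unknown record codec {codec!r}")


def record_decompress(blob: bytes, codec: str) -> bytes:
    if codec == "none":
        return bytes(blob)
    if codec == "zlib":
        try:
            return zlib.decompress(bytes(blob))
        except zlib.error as e:
            raise MalformedPayloadError(f"zlib payload invalid: {e}") from e
    if codec == "zstd":
        pa = _zstd()
        if len(blob) < _COUNT.size:
            raise MalformedPayloadError("zstd container shorter than its header")
        (raw_len,) = _COUNT.unpack_from(blob, 0)
        try:
            out = pa.decompress(bytes(blob[_COUNT.size:]), decompressed_size=raw_len,
                                codec="zstd", asbytes=True)
        except Exception as e:
            raise MalformedPayloadError(f"zstd payload invalid: {e}") from e
        return out
    raise CodecUnavailableError(f"unknown record codec {codec!r}")
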