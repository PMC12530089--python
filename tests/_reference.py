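"""Naive scalar reference implementations used as independent oracles.

These are intentionally written as plain per-value Python loops, sharing no
code with the package's vectorised implementations.
"""

import struct


def ref_pa_convert(raw, offset, rng, digitisation):
    return [(r + offset) * rng / digitisation for r in raw]


def ref_zigzag_delta(signal):
    out = []
    prev = 0
    for s in signal:
        d = (int(s) - prev) & 0xFFFF  # 16-bit wraparound difference
        if d >= 0x8000:
            d -= 0x10000
        out.append(((d << 1) ^ (d >> 15)) & 0xFFFFFFFF)
        prev = int(s)
    return out


def ref_inverse_zigzag_delta(values):
    out = []
    prev = 0
    for z in values:
        d = (z >> 1) ^ -(z & 1)
        s = (prev + d) & 0xFFFF
        if s >= 0x8000:
            s -= 0x10000
        out.append(s)
        prev = s
    return out


def _byte_len(v, max_bytes):
    n = 1
    while v >= (1 << (8 * n)):
        n += 1
    if n > max_bytes:
        raise ValueError(f"{v} needs {n} bytes > {max_bytes}")
    return n


def ref_svb_encode(values, max_bytes):
    """Scalar stream-variable-byte encoder (max_bytes 2 or 4)."""
    n = len(values)
    out = bytearray(struct.pack("<Q", n))
    lens = [_byte_len(int(v), max_bytes) for v in values]
    if max_bytes == 2:
        for g in range(0, n, 8):
            byte = 0
            for j, ln in enumerate(lens[g:g + 8]):
                byte |= (ln - 1) << j
            out.append(byte)
    else:
        for g in range(0, n, 4):
            byte = 0
            for j, ln in enumerate(lens[g:g + 4]):
                byte |= (ln - 1) << (2 * j)
            out.append(byte)
    for v, ln in zip(values, lens):
        out += int(v).to_bytes(ln, "little")
    return bytes(out)


def ref_svb_decode(payload, max_bytes):
    (n,) = struct.unpack_from("<Q", payload, 0)
    per_byte = 8 if max_bytes == 2 else 4
    n_ctrl = (n + per_byte - 1) // per_byte
    ctrl = payload[8:8 + n_ctrl]
    lens = []
    for i in range(n):
        byte = ctrl[i // per_byte]
        if max_bytes == 2:
            lens.append(((byte >> (i % 8)) & 1) + 1)
        else:
            lens.append(((byte >> (2 * (i % 4))) & 3) + 1)
    pos = 8 + n_ctrl
    values = []
    for ln in lens:
        values.append(int.from_bytes(payload[pos:pos + ln], "little"))
        pos += ln
    assert pos == len(payload), "trailing bytes"
    return values
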