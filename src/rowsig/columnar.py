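"""Column-oriented, chunk-interleaved comparator container (``.colsig``).

This is a deliberately minimal stand-in for column-based signal containers:
each metadata attribute is stored contiguously for all reads, and raw signal
is stored in fixed-size chunks (default 102,400 samples) that may be
interspersed between reads. It exists so the benchmark harness can contrast
row-based against column/chunk-based access patterns with both containers
decoding to identical record sets. It makes no attempt at Arrow framing or
per-chunk compression — the layout is the variable under study.

Retrieval is index-free, by a two-pass *walker*: pass 1 traverses the whole
file to build an in-memory lookup table of every read's chunk and column
locations; pass 2 fetches the requested reads, one seek per non-adjacent
region (each chunk, each attribute column).

Layout (little-endian)::

    magic "COLSIG01"
    header_blob_len (u32)  header_blob
    chunk_size (u64)
    signal region: repeat [read_ord (u32) chunk_ord (u32) n_samples (u32) data]
    column region: one contiguous block per column (fixed-width values, or a
                   u64 offsets array plus a byte heap for variable columns)
    footer: chunk table + column directory
    footer_offset (u64)  tail magic "COLSIGFT"
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from . import binary_io
from ._util import CountingFile, read_exact
from .errors import (
    ConfigError,
    CorruptionError,
    ReadNotFoundError,
)
from .model import FileHeader, ReadRecord

MAGIC = b"COLSIG01"
TAIL_MAGIC = b"COLSIGFT"
DEFAULT_CHUNK_SIZE = 102_400

_U8 = struct.Struct("<B")
_U32 = struct.Struct("<I")
_U64 = struct.Struct("<Q")
_CHUNK_HDR = struct.Struct("<III")

# (name, numpy dtype) for the fixed-width attribute columns.
FIXED_COLUMNS = (
    ("read_group", "<u4"),
    ("digitisation", "<f8"),
    ("offset", "<f8"),
    ("range", "<f8"),
    ("sampling_rate", "<f8"),
    ("len_raw_signal", "<u8"),
    ("median_before", "<f8"),
    ("read_number", "<u4"),
    ("start_mux", "u1"),
    ("start_time", "<u8"),
)
VARIABLE_COLUMNS = ("read_id", "channel_number", "extras")
N_ATTRIBUTE_COLUMNS = len(FIXED_COLUMNS) + len(VARIABLE_COLUMNS)


def n_chunks(length: int, chunk_size: int) -> int:
    return max(1, math.ceil(length / chunk_size)) if length else 0


# ---------------------------------------------------------------- writing ---

def _chunk_slices(sig: np.ndarray, chunk_size: int):
    for ord_ in range(n_chunks(sig.size, chunk_size)):
        yield ord_, sig[ord_ * chunk_size:(ord_ + 1) * chunk_size]


def write_columnar(header: FileHeader, reads: Iterable[ReadRecord], sink,
                   interleave_policy: str = "contiguous",
                   chunk_size: int = DEFAULT_CHUNK_SIZE,
                   round_robin_width: int = 4) -> int:
    """Write records to a columnar file; returns the number of reads.

    ``interleave_policy``: ``contiguous`` writes each read's chunks
    back-to-back; ``round_robin`` keeps up to ``round_robin_width`` reads
    open simultaneously and cycles one chunk from each, creating the
    interspersed layout deterministically.
    """
    if chunk_size < 1:
        raise ConfigError("chunk_size must be >= 1")
    if interleave_policy not in ("contiguous", "round_robin"):
        raise ConfigError(f"unknown interleave policy {interleave_policy!r}")
    header.validate()

    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        f = open(sink, "wb")
        owns = True
    else:
        f, owns = sink, False
    try:
        return _write(f, header, reads, interleave_policy, chunk_size,
                      round_robin_width)
    finally:
        if owns:
            f.close()


def _write(f, header, reads, policy, chunk_size, width) -> int:
    hdr_blob = binary_io._serialize_header(header)
    f.write(MAGIC)
    f.write(_U32.pack(len(hdr_blob)))
    f.write(hdr_blob)
    f.write(_U64.pack(chunk_size))

    cols: dict[str, list] = {name: [] for name, _ in FIXED_COLUMNS}
    ids: list[bytes] = []
    chans: list[bytes] = []
    extras: list[bytes] = []
    chunk_offsets: list[list[int]] = []

    def admit(rec: ReadRecord) -> int:
        rec.validate()
        ord_ = len(ids)
        ids.append(rec.read_id.encode("ascii"))
        chans.append(rec.channel_number.encode("ascii"))
        extras.append(json.dumps(rec.extras, sort_keys=True).encode("ascii"))
        cols["read_group"].append(rec.read_group)
        cols["digitisation"].append(rec.digitisation)
        cols["offset"].append(rec.offset)
        cols["range"].append(rec.range)
        cols["sampling_rate"].append(rec.sampling_rate)
        cols["len_raw_signal"].append(rec.len_raw_signal)
        cols["median_before"].append(rec.median_before)
        cols["read_number"].append(rec.read_number)
        cols["start_mux"].append(rec.start_mux)
        cols["start_time"].append(rec.start_time)
        chunk_offsets.append([])
        return ord_

    def emit_chunk(ord_: int, chunk_ord: int, data: np.ndarray) -> None:
        chunk_offsets[ord_].append(f.tell())
        f.write(_CHUNK_HDR.pack(ord_, chunk_ord, data.size))
        f.write(np.ascontiguousarray(data, dtype="<i2").tobytes())

    reads = iter(reads)
    if policy == "contiguous":
        for rec in reads:
            ord_ = admit(rec)
            for c_ord, piece in _chunk_slices(rec.raw_signal, chunk_size):
                emit_chunk(ord_, c_ord, piece)
    else:
        window: list[tuple[int, Iterator]] = []
        exhausted = False
        while window or not exhausted:
            while not exhausted and len(window) < width:
                rec = next(reads, None)
                if rec is None:
                    exhausted = True
                    break
                ord_ = admit(rec)
                window.append((ord_, iter(_chunk_slices(rec.raw_signal,
                                                        chunk_size))))
            still_open = []
            for ord_, it in window:
                item = next(it, None)
                if item is not None:
                    emit_chunk(ord_, item[0], item[1])
                    still_open.append((ord_, it))
            window = still_open

    n = len(ids)
    directory: list[tuple[str, int, int, int]] = []  # name, offset, length, kind

    for name, dtype in FIXED_COLUMNS:
        arr = np.asarray(cols[name], dtype=dtype)
        off = f.tell()
        f.write(arr.tobytes())
        directory.append((name, off, arr.nbytes, 0))
    for name, blobs in (("read_id", ids), ("channel_number", chans),
                        ("extras", extras)):
        offsets = np.zeros(n + 1, dtype="<u8")
        np.cumsum([len(b) for b in blobs], out=offsets[1:])
        off = f.tell()
        f.write(offsets.tobytes())
        directory.append((name + ".offsets", off, offsets.nbytes, 1))
        off = f.tell()
        heap = b"".join(blobs)
        f.write(heap)
        directory.append((name + ".heap", off, len(heap), 2))

    footer_offset = f.tell()
    f.write(_U64.pack(n))
    for offs in chunk_offsets:
        f.write(_U32.pack(len(offs)))
        for o in offs:
            f.write(_U64.pack(o))
    f.write(_U32.pack(len(directory)))
    for name, off, length, kind in directory:
        nb = name.encode("ascii")
        f.write(_U8.pack(len(nb)) + nb + _U64.pack(off) + _U64.pack(length)
                + _U8.pack(kind))
    f.write(_U64.pack(footer_offset))
    f.write(TAIL_MAGIC)
    return n


# ---------------------------------------------------------------- reading ---

@dataclass
class _Layout:
    header: FileHeader
    chunk_size: int
    n_reads: int
    chunk_offsets: list[list[int]]
    columns: dict[str, tuple[int, int, int]]  # name -> (offset, length, kind)
    signal_start: int


def _read_layout(f) -> _Layout:
    f.seek(0)
    if read_exact(f, len(MAGIC)) != MAGIC:
        raise CorruptionError("bad columnar magic")
    (hlen,) = _U32.unpack(read_exact(f, 4))
    header = binary_io._deserialize_header(read_exact(f, hlen), "none", "none")
    (chunk_size,) = _U64.unpack(read_exact(f, 8))
    signal_start = f.tell()

    f.seek(-16, 2)
    tail = read_exact(f, 16)
    if tail[8:] != TAIL_MAGIC:
        raise CorruptionError("missing columnar tail magic")
    (footer_offset,) = _U64.unpack_from(tail, 0)
    f.seek(footer_offset)
    (n,) = _U64.unpack(read_exact(f, 8))
    chunk_offsets = []
    for _ in range(n):
        (k,) = _U32.unpack(read_exact(f, 4))
        offs = np.frombuffer(read_exact(f, 8 * k), dtype="<u8").tolist()
        chunk_offsets.append(offs)
    (ncols,) = _U32.unpack(read_exact(f, 4))
    columns = {}
    for _ in range(ncols):
        (nlen,) = _U8.unpack(read_exact(f, 1))
        name = read_exact(f, nlen).decode("ascii")
        (off,) = _U64.unpack(read_exact(f, 8))
        (length,) = _U64.unpack(read_exact(f, 8))
        (kind,) = _U8.unpack(read_exact(f, 1))
        columns[name] = (off, length, kind)
    return _Layout(header, chunk_size, n, chunk_offsets, columns, signal_start)


def _load_columns(f, layout: _Layout):
    fixed = {}
    for name, dtype in FIXED_COLUMNS:
        off, length, _ = layout.columns[name]
        f.seek(off)
        fixed[name] = np.frombuffer(read_exact(f, length), dtype=dtype)
    var = {}
    for name in VARIABLE_COLUMNS:
        ooff, olen, _ = layout.columns[name + ".offsets"]
        hoff, hlen, _ = layout.columns[name + ".heap"]
        f.seek(ooff)
        offsets = np.frombuffer(read_exact(f, olen), dtype="<u8")
        f.seek(hoff)
        heap = read_exact(f, hlen)
        var[name] = (offsets, heap)
    return fixed, var


def _var_value(var, name: str, ord_: int) -> str:
    offsets, heap = var[name]
    return heap[int(offsets[ord_]):int(offsets[ord_ + 1])].decode("ascii")


def _make_record(ord_: int, fixed, var, signal: np.ndarray) -> ReadRecord:
    return ReadRecord(
        read_id=_var_value(var, "read_id", ord_),
        read_group=int(fixed["read_group"][ord_]),
        digitisation=float(fixed["digitisation"][ord_]),
        offset=float(fixed["offset"][ord_]),
        range=float(fixed["range"][ord_]),
        sampling_rate=float(fixed["sampling_rate"][ord_]),
        raw_signal=signal,
        channel_number=_var_value(var, "channel_number", ord_),
        median_before=float(fixed["median_before"][ord_]),
        read_number=int(fixed["read_number"][ord_]),
        start_mux=int(fixed["start_mux"][ord_]),
        start_time=int(fixed["start_time"][ord_]),
        extras=json.loads(_var_value(var, "extras", ord_)),
    )


def read_columnar(source) -> tuple[FileHeader, Iterator[ReadRecord]]:
    """Decode the whole file; records yielded in original (ordinal) order.

    The signal region is traversed sequentially; partially assembled reads
    are buffered until complete, so memory stays bounded by the writer's
    interleaving width.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        f = open(source, "rb")
        owns = True
    else:
        f, owns = source, False
    layout = _read_layout(f)
    fixed, var = _load_columns(f, layout)

    def gen() -> Iterator[ReadRecord]:
        try:
            lens = fixed["len_raw_signal"]
            partial: dict[int, np.ndarray] = {}
            remaining: dict[int, int] = {}
            done: dict[int, np.ndarray] = {}
            next_emit = 0
            total_chunks = sum(len(c) for c in layout.chunk_offsets)
            f.seek(layout.signal_start)
            for _ in range(total_chunks):
                ord_, c_ord, nsamp = _CHUNK_HDR.unpack(
                    read_exact(f, _CHUNK_HDR.size))
                data = np.frombuffer(read_exact(f, 2 * nsamp), dtype="<i2")
                if ord_ not in partial:
                    partial[ord_] = np.empty(int(lens[ord_]), dtype=np.int16)
                    remaining[ord_] = int(lens[ord_])
                start = c_ord * layout.chunk_size
                partial[ord_][start:start + nsamp] = data
                remaining[ord_] -= nsamp
                if remaining[ord_] == 0:
                    done[ord_] = partial.pop(ord_)
                    del remaining[ord_]
                while next_emit in done:
                    yield _make_record(next_emit, fixed, var,
                                       done.pop(next_emit))
                    next_emit += 1
            # zero-length reads never appear in the signal region
            for ord_ in range(next_emit, layout.n_reads):
                if ord_ in done:
                    yield _make_record(ord_, fixed, var, done.pop(ord_))
                elif int(lens[ord_]) == 0:
                    yield _make_record(ord_, fixed, var,
                                       np.zeros(0, dtype=np.int16))
                else:
                    raise CorruptionError(
                        f"read ordinal {ord_} is missing signal chunks")
        finally:
            if owns:
                f.close()

    return layout.header, gen()


# ----------------------------------------------------------------- walker ---

@dataclass
class WalkerStats:
    pass1_seeks: int
    pass2_seeks: int
    reads: int
    chunks_fetched: int

    @property
    def seeks(self) -> int:
        return self.pass1_seeks + self.pass2_seeks


def walker_fetch(source, read_ids, return_stats: bool = False):
    """Index-free two-pass retrieval.

    Pass 1 traverses the complete file — every chunk header in the signal
    region plus the footer and ID column — building a lookup table for *all*
    reads. Pass 2 fetches the requested reads in request order, seeking to
    each signal chunk and each attribute column entry individually.
    """
    with open(source, "rb") as rawf:
        f = CountingFile(rawf)
        layout = _read_layout(f)

        # Pass 1: walk the signal region chunk headers.
        lookup: dict[int, list[tuple[int, int, int]]] = {}
        f.seek(layout.signal_start)
        total_chunks = sum(len(c) for c in layout.chunk_offsets)
        for _ in range(total_chunks):
            pos = f.tell()
            ord_, c_ord, nsamp = _CHUNK_HDR.unpack(read_exact(f, _CHUNK_HDR.size))
            lookup.setdefault(ord_, []).append((c_ord, pos, nsamp))
            f.seek(2 * nsamp, 1)
        # ID column completes the lookup table.
        ooff, olen, _ = layout.columns["read_id.offsets"]
        hoff, hlen, _ = layout.columns["read_id.heap"]
        f.seek(ooff)
        id_offsets = np.frombuffer(read_exact(f, olen), dtype="<u8")
        f.seek(hoff)
        id_heap = read_exact(f, hlen)
        ordinal_of = {}
        for i in range(layout.n_reads):
            rid = id_heap[int(id_offsets[i]):int(id_offsets[i + 1])].decode("ascii")
            ordinal_of[rid] = i
        pass1_seeks = f.seeks

        # Pass 2: per-read random access.
        records: list[ReadRecord] = []
        chunks_fetched = 0
        fixed_dtypes = dict(FIXED_COLUMNS)
        for rid in read_ids:
            ord_ = ordinal_of.get(rid)
            if ord_ is None:
                raise ReadNotFoundError(f"read ID {rid!r} not present")
            fields: dict[str, object] = {}
            for name, dtype in FIXED_COLUMNS:
                width = np.dtype(dtype).itemsize
                off, _, _ = layout.columns[name]
                f.seek(off + ord_ * width)
                fields[name] = np.frombuffer(read_exact(f, width),
                                             dtype=fixed_dtypes[name])[0]
            for name in ("channel_number", "extras"):
                voff, _, _ = layout.columns[name + ".offsets"]
                f.seek(voff + 8 * ord_)
                lo, hi = np.frombuffer(read_exact(f, 16), dtype="<u8")
                heap_off, _, _ = layout.columns[name + ".heap"]
                f.seek(heap_off + int(lo))
                fields[name] = read_exact(f, int(hi - lo)).decode("ascii")
            length = int(fields["len_raw_signal"])
            signal = np.empty(length, dtype=np.int16)
            for c_ord, pos, nsamp in sorted(lookup.get(ord_, [])):
                f.seek(pos + _CHUNK_HDR.size)
                start = c_ord * layout.chunk_size
                signal[start:start + nsamp] = np.frombuffer(
                    read_exact(f, 2 * nsamp), dtype="<i2")
                chunks_fetched += 1
            records.append(ReadRecord(
                read_id=rid,
                read_group=int(fields["read_group"]),
                digitisation=float(fields["digitisation"]),
                offset=float(fields["offset"]),
                range=float(fields["range"]),
                sampling_rate=float(fields["sampling_rate"]),
                raw_signal=signal,
                channel_number=str(fields["channel_number"]),
                median_before=float(fields["median_before"]),
                read_number=int(fields["read_number"]),
                start_mux=int(fields["start_mux"]),
                start_time=int(fields["start_time"]),
                extras=json.loads(str(fields["extras"])),
            ))
        stats = WalkerStats(pass1_seeks=pass1_seeks,
                            pass2_seeks=f.seeks - pass1_seeks,
                            reads=len(records),
                            chunks_fetched=chunks_fetched)
    if return_stats:
        return records, stats
    return records
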