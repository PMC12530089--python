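"""Binary dialect (``.blow5``): length-prefixed, per-record-compressed rows.

File layout (all integers little-endian)::

    magic (8 bytes)
    record_codec (u8)  signal_codec (u8)
    header_blob_len (u32)  header_blob (record_codec-compressed)
    repeat:  record_len (u32)  compressed_record (record_len bytes)
    eof marker (8 bytes: u32 0xFFFFFFFF + b"END!")

The record length prefix can never legitimately be 0xFFFFFFFF, which is why
that value doubles as the end-of-file sentinel. A file is valid only if it
ends with the marker and nothing follows it.

Each record decompresses independently to::

    read_id_len (u16)  read_id (ascii)
    read_group (u32)
    digitisation, offset, range, sampling_rate (4 x f64)
    len_raw_signal (u64)
    signal_len (u64)  signal payload (signal_codec-compressed)
    aux field count (u16), then per field:
        key_len (u8)  key  type (u8)  value

Auxiliary values are a typed TLV block (types: str, f64, u32, u8, u64) so
unknown fields survive round trips.
"""

from __future__ import annotations

import contextlib
import struct
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from . import codec as _codec
from .errors import (
    CorruptionError,
    DuplicateReadIDError,
    SerializationError,
    TruncatedFileError,
    ValidationError,
)
from ._util import read_exact
from .model import FileHeader, ReadRecord

MAGIC = b"\x8fROWSIG\x01"
EOF_MARKER = struct.pack("<I", 0xFFFFFFFF) + b"END!"

_U8 = struct.Struct("<B")
_U16 = struct.Struct("<H")
_U32 = struct.Struct("<I")
_U64 = struct.Struct("<Q")
_F64 = struct.Struct("<d")
_CALIB = struct.Struct("<dddd")

_T_STR, _T_F64, _T_U32, _T_U8, _T_U64 = 1, 2, 3, 4, 5

_RECORD_CODEC_IDS = {"none": 0, "zlib": 1, "zstd": 2}
_SIGNAL_CODEC_IDS = {"none": 0, "svb32-zd": 1, "svb16-zd": 2}
_RECORD_CODEC_NAMES = {v: k for k, v in _RECORD_CODEC_IDS.items()}
_SIGNAL_CODEC_NAMES = {v: k for k, v in _SIGNAL_CODEC_IDS.items()}


@dataclass
class WriteSummary:
    records: int
    bytes: int


# ---------------------------------------------------------------- header ----

def _serialize_header(header: FileHeader) -> bytes:
    out = [bytes(header.version)]
    out.append(_U32.pack(header.num_read_groups))
    out.append(_U32.pack(len(header.attributes)))
    for key, values in header.attributes.items():
        kb = key.encode("ascii")
        out.append(_U16.pack(len(kb)) + kb)
        for v in values:
            vb = v.encode("ascii")
            out.append(_U32.pack(len(vb)) + vb)
    return b"".join(out)


def _deserialize_header(blob: bytes, record_codec: str,
                        signal_codec: str) -> FileHeader:
    version = tuple(blob[:3])
    off = 3
    (num_groups,) = _U32.unpack_from(blob, off)
    off += 4
    (n_attrs,) = _U32.unpack_from(blob, off)
    off += 4
    attributes: dict[str, list[str]] = {}
    for _ in range(n_attrs):
        (klen,) = _U16.unpack_from(blob, off)
        off += 2
        key = blob[off:off + klen].decode("ascii")
        off += klen
        values = []
        for _ in range(num_groups):
            (vlen,) = _U32.unpack_from(blob, off)
            off += 4
            values.append(blob[off:off + vlen].decode("ascii"))
            off += vlen
        attributes[key] = values
    return FileHeader(version=version, record_codec=record_codec,
                      signal_codec=signal_codec, num_read_groups=num_groups,
                      attributes=attributes)


# ---------------------------------------------------------------- records ---

def _encode_aux(rec: ReadRecord) -> bytes:
    fields: list[tuple[str, int, bytes]] = [
        ("channel_number", _T_STR, rec.channel_number.encode("ascii")),
        ("median_before", _T_F64, _F64.pack(rec.median_before)),
        ("read_number", _T_U32, _U32.pack(rec.read_number)),
        ("start_mux", _T_U8, _U8.pack(rec.start_mux)),
        ("start_time", _T_U64, _U64.pack(rec.start_time)),
    ]
    for key in sorted(rec.extras):
        fields.append((key, _T_STR, rec.extras[key].encode("ascii")))
    out = [_U16.pack(len(fields))]
    for key, typ, payload in fields:
        kb = key.encode("ascii")
        if len(kb) > 255:
            raise SerializationError(f"aux key too long: {key!r}")
        out.append(_U8.pack(len(kb)) + kb + _U8.pack(typ))
        if typ == _T_STR:
            out.append(_U32.pack(len(payload)))
        out.append(payload)
    return b"".join(out)


def encode_record(rec: ReadRecord, signal_codec: str) -> bytes:
    """Serialize one record (uncompressed form, before the record codec)."""
    rec.validate()
    rid = rec.read_id.encode("ascii")
    sig_payload = _codec.compress_signal(rec.raw_signal, signal_codec)
    return b"".join([
        _U16.pack(len(rid)), rid,
        _U32.pack(rec.read_group),
        _CALIB.pack(rec.digitisation, rec.offset, rec.range, rec.sampling_rate),
        _U64.pack(rec.len_raw_signal),
        _U64.pack(len(sig_payload)), sig_payload,
        _encode_aux(rec),
    ])


def decode_record(blob: bytes, signal_codec: str) -> ReadRecord:
    try:
        (rid_len,) = _U16.unpack_from(blob, 0)
        off = 2
        read_id = blob[off:off + rid_len].decode("ascii")
        off += rid_len
        (read_group,) = _U32.unpack_from(blob, off)
        off += 4
        digitisation, offset_v, range_v, sampling_rate = _CALIB.unpack_from(blob, off)
        off += _CALIB.size
        (len_raw,) = _U64.unpack_from(blob, off)
        off += 8
        (sig_len,) = _U64.unpack_from(blob, off)
        off += 8
        signal = _codec.decompress_signal(blob[off:off + sig_len], signal_codec)
        off += sig_len
        (n_aux,) = _U16.unpack_from(blob, off)
        off += 2
        aux: dict[str, object] = {}
        extras: dict[str, str] = {}
        for _ in range(n_aux):
            (klen,) = _U8.unpack_from(blob, off)
            off += 1
            key = blob[off:off + klen].decode("ascii")
            off += klen
            (typ,) = _U8.unpack_from(blob, off)
            off += 1
            if typ == _T_STR:
                (vlen,) = _U32.unpack_from(blob, off)
                off += 4
                val: object = blob[off:off + vlen].decode("ascii")
                off += vlen
            elif typ == _T_F64:
                (val,) = _F64.unpack_from(blob, off)
                off += 8
            elif typ == _T_U32:
                (val,) = _U32.unpack_from(blob, off)
                off += 4
            elif typ == _T_U8:
                (val,) = _U8.unpack_from(blob, off)
                off += 1
            elif typ == _T_U64:
                (val,) = _U64.unpack_from(blob, off)
                off += 8
            else:
                raise CorruptionError(f"unknown aux type {typ}")
            if key in ("channel_number", "median_before", "read_number",
                       "start_mux", "start_time"):
                aux[key] = val
            else:
                extras[key] = str(val)
    except struct.error as e:
        raise CorruptionError(f"record blob too short: {e}") from e
    if len_raw != signal.size:
        raise CorruptionError(
            f"read {read_id!r}: len_raw_signal={len_raw} but signal decoded "
            f"to {signal.size} samples"
        )
    return ReadRecord(
        read_id=read_id, read_group=read_group, digitisation=digitisation,
        offset=offset_v, range=range_v, sampling_rate=sampling_rate,
        raw_signal=signal,
        channel_number=aux.get("channel_number", ""),
        median_before=aux.get("median_before", float("nan")),
        read_number=aux.get("read_number", 0),
        start_mux=aux.get("start_mux", 1),
        start_time=aux.get("start_time", 0),
        extras=extras,
    )


# ---------------------------------------------------------------- writer ----

class BinaryWriter:
    """Streaming writer with explicit finalization.

    The end-of-file marker is written on :meth:`close`; the simulator keeps
    writers open across its whole run and appends records incrementally.
    """

    def __init__(self, sink, header: FileHeader):
        header.validate()
        self.header = header
        if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
            self._f = open(sink, "wb")
            self._owns = True
        else:
            self._f = sink
            self._owns = False
        self.records = 0
        self.bytes = 0
        blob = _codec.record_compress(_serialize_header(header),
                                      header.record_codec)
        self._f.write(MAGIC)
        self._f.write(_U8.pack(_RECORD_CODEC_IDS[header.record_codec]))
        self._f.write(_U8.pack(_SIGNAL_CODEC_IDS[header.signal_codec]))
        self._f.write(_U32.pack(len(blob)))
        self._f.write(blob)
        self._finalized = False

    def write(self, rec: ReadRecord) -> int:
        if rec.read_group >= self.header.num_read_groups:
            raise SerializationError(
                f"read {rec.read_id!r}: read_group {rec.read_group} >= "
                f"num_read_groups {self.header.num_read_groups}"
            )
        blob = _codec.record_compress(
            encode_record(rec, self.header.signal_codec),
            self.header.record_codec)
        if len(blob) >= 0xFFFFFFFF:
            raise SerializationError("record exceeds the 4 GiB framing limit")
        self._f.write(_U32.pack(len(blob)))
        self._f.write(blob)
        self.records += 1
        self.bytes += 4 + len(blob)
        return 4 + len(blob)

    def flush(self) -> None:
        self._f.flush()

    def tell(self) -> int:
        return self._f.tell()

    def close(self) -> None:
        if not self._finalized:
            self._f.write(EOF_MARKER)
            self._f.flush()
            self._finalized = True
        if self._owns:
            self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


def write_binary(header: FileHeader, reads: Iterable[ReadRecord],
                 sink) -> WriteSummary:
    """Write a complete, finalized binary file; returns (records, bytes)."""
    with BinaryWriter(sink, header) as w:
        for rec in reads:
            w.write(rec)
        total = w.tell() + len(EOF_MARKER)
        return WriteSummary(records=w.records, bytes=total)


def open_binary_append(path) -> BinaryWriter:
    """Reopen a finalized file for appending.

    The existing end-of-file marker is verified and truncated away; appending
    to a file whose marker is missing (or already followed by extra bytes) is
    refused.
    """
    with open(path, "rb") as f:
        header, data_start = read_header(f)
        f.seek(0, 2)
        size = f.tell()
        if size < data_start + len(EOF_MARKER):
            raise TruncatedFileError(f"{path}: no end-of-file marker to truncate")
        f.seek(size - len(EOF_MARKER))
        if f.read(len(EOF_MARKER)) != EOF_MARKER:
            raise CorruptionError(
                f"{path}: file is not finalized; refusing to append")
    fobj = open(path, "r+b")
    fobj.truncate(size - len(EOF_MARKER))
    fobj.seek(size - len(EOF_MARKER))
    w = BinaryWriter.__new__(BinaryWriter)
    w.header = header
    w._f = fobj
    w._owns = True
    w.records = 0
    w.bytes = 0
    w._finalized = False
    return w


# ---------------------------------------------------------------- reader ----

def read_header(f) -> tuple[FileHeader, int]:
    """Read and validate the file prologue; returns (header, data offset)."""
    magic = read_exact(f, len(MAGIC))
    if magic != MAGIC:
        raise CorruptionError(f"bad magic {magic!r}")
    (rc_id,) = _U8.unpack(read_exact(f, 1))
    (sc_id,) = _U8.unpack(read_exact(f, 1))
    if rc_id not in _RECORD_CODEC_NAMES or sc_id not in _SIGNAL_CODEC_NAMES:
        raise CorruptionError(f"unknown codec ids ({rc_id}, {sc_id})")
    record_codec = _RECORD_CODEC_NAMES[rc_id]
    signal_codec = _SIGNAL_CODEC_NAMES[sc_id]
    (blob_len,) = _U32.unpack(read_exact(f, 4))
    blob = _codec.record_decompress(read_exact(f, blob_len), record_codec)
    header = _deserialize_header(blob, record_codec, signal_codec)
    return header, f.tell()


def iter_framed(f, file_size: int | None = None,
                tolerate_unterminated: bool = False) -> Iterator[tuple[int, bytes]]:
    """Yield (offset, compressed_record) for each framed record.

    ``f`` must be positioned at the first record. With
    ``tolerate_unterminated`` the iterator stops quietly at end of data (used
    for reading files still being written); otherwise a missing end marker
    raises :class:`TruncatedFileError` and trailing bytes after the marker
    raise :class:`CorruptionError`.
    """
    if file_size is None:
        pos = f.tell()
        f.seek(0, 2)
        file_size = f.tell()
        f.seek(pos)
    while True:
        offset = f.tell()
        prefix = f.read(4)
        if len(prefix) < 4:
            if tolerate_unterminated:
                return
            raise TruncatedFileError("file ends without an end-of-file marker")
        (rec_len,) = _U32.unpack(prefix)
        if rec_len == 0xFFFFFFFF:
            tail = f.read(4)
            if tail != EOF_MARKER[4:]:
                if tolerate_unterminated:
                    return
                raise CorruptionError("malformed end-of-file marker")
            if f.read(1):
                raise CorruptionError(
                    "trailing bytes after the end-of-file marker (file was "
                    "appended to without truncating the marker)")
            return
        if offset + 4 + rec_len > file_size:
            if tolerate_unterminated:
                return
            raise CorruptionError(
                f"record at offset {offset} ({rec_len} bytes) overruns the file")
        blob = read_exact(f, rec_len)
        yield offset, blob


@contextlib.contextmanager
def _open_binary(source):
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        f = open(source, "rb")
        try:
            yield f
        finally:
            f.close()
    else:
        yield source


def read_binary_raw_batches(source, batch_size: int = 1000
                            ) -> Iterator[tuple[FileHeader, list[bytes]]]:
    """Yield (header, batch-of-compressed-blobs); I/O stays in the caller's
    thread, decode can be fanned out elsewhere."""
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    with _open_binary(source) as f:
        header, _ = read_header(f)
        batch: list[bytes] = []
        for _, blob in iter_framed(f):
            batch.append(blob)
            if len(batch) == batch_size:
                yield header, batch
                batch = []
        if batch:
            yield header, batch


def decode_batch(header: FileHeader, blobs: list[bytes],
                 first_index: int = 0) -> list[ReadRecord]:
    out = []
    for k, blob in enumerate(blobs):
        try:
            raw = _codec.record_decompress(blob, header.record_codec)
            out.append(decode_record(raw, header.signal_codec))
        except Exception as e:
            raise CorruptionError(
                f"record {first_index + k} failed to decode: {e}") from e
    return out


def read_binary_sequential(source, batch_size: int = 1000
                           ) -> Iterator[list[ReadRecord]]:
    """Yield decoded record batches of at most ``batch_size``, in file order."""
    n = 0
    for header, blobs in read_binary_raw_batches(source, batch_size):
        yield decode_batch(header, blobs, first_index=n)
        n += len(blobs)


def parallel_decode(source, batch_size: int = 1000,
                    n_workers: int = 1) -> Iterator[ReadRecord]:
    """Sequential framing reads + worker-pool record decode.

    Batches are handed to a thread pool for decompression/parse and emitted
    in file order regardless of worker scheduling, so the output is identical
    to a single-threaded sequential read.
    """
    if n_workers < 1:
        raise ValidationError("n_workers must be >= 1")
    if n_workers == 1:
        for batch in read_binary_sequential(source, batch_size):
            yield from batch
        return
    from collections import deque
    from concurrent.futures import ThreadPoolExecutor

    def work(i, header, blobs):
        try:
            return decode_batch(header, blobs, first_index=i * batch_size)
        except Exception as e:
            raise CorruptionError(f"batch {i} failed: {e}") from e

    # Bounded in-flight window: file-order emission without buffering the
    # whole file's raw blobs in memory.
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        pending: deque = deque()
        source_iter = enumerate(read_binary_raw_batches(source, batch_size))
        exhausted = False
        while True:
            while not exhausted and len(pending) < 2 * n_workers:
                try:
                    i, (header, blobs) = next(source_iter)
                except StopIteration:
                    exhausted = True
                    break
                pending.append(pool.submit(work, i, header, blobs))
            if not pending:
                return
            yield from pending.popleft().result()


def read_binary(source) -> tuple[FileHeader, list[ReadRecord]]:
    """Convenience: header plus all records of a (small) file."""
    with _open_binary(source) as f:
        header, _ = read_header(f)
        records: list[ReadRecord] = []
        for _, blob in iter_framed(f):
            raw = _codec.record_decompress(blob, header.record_codec)
            records.append(decode_record(raw, header.signal_codec))
        return header, records


def scan_read_ids(source) -> list[str]:
    """Read IDs in file order, decoding only as far as each record's ID."""
    ids: list[str] = []
    seen = set()
    with _open_binary(source) as f:
        header, _ = read_header(f)
        for _, blob in iter_framed(f):
            raw = _codec.record_decompress(blob, header.record_codec)
            (rid_len,) = _U16.unpack_from(raw, 0)
            rid = raw[2:2 + rid_len].decode("ascii")
            if rid in seen:
                raise DuplicateReadIDError(f"duplicate read ID {rid!r}")
            seen.add(rid)
            ids.append(rid)
    return ids
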