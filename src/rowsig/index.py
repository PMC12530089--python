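"""Read-ID index sidecar (``.blow5.idx``) and single-seek random access.

The index maps each read ID to the byte position of its framed record (the
offset of the length prefix) and the total framed length, so fetching any
read costs exactly one seek plus one bounded read. The sidecar records the
data file's size and a checksum of its prologue; a mismatch on load means the
data file changed since indexing and the index is refused as stale — silent
wrong-offset reads are the worst possible failure mode.

Sidecar layout: magic ``RWSGIDX1``, then a zlib-compressed body::

    data_file_size (u64)  header_crc32 (u32)  entry_count (u64)
    repeat: id_len (u16)  id  offset (u64)  length (u32)
"""

from __future__ import annotations

import os
import struct
import zlib
from dataclasses import dataclass

from . import binary_io
from ._util import CountingFile, read_exact
from .codec import record_decompress
from .errors import (
    CorruptionError,
    DuplicateReadIDError,
    ReadNotFoundError,
    StaleIndexError,
)
from .model import ReadRecord

INDEX_MAGIC = b"RWSGIDX1"
_U16 = struct.Struct("<H")
_U32 = struct.Struct("<I")
_U64 = struct.Struct("<Q")


@dataclass
class IndexEntry:
    read_id: str
    offset: int
    length: int


@dataclass
class Index:
    data_file_size: int
    header_crc: int
    entries: dict[str, tuple[int, int]]  # read_id -> (offset, framed length)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.entries


def index_path_for(binary_path) -> str:
    return os.fspath(binary_path) + ".idx"


def _prologue_crc(f) -> int:
    """CRC32 of the file prologue (magic through header blob)."""
    f.seek(0)
    binary_io.read_header(f)
    end = f.tell()
    f.seek(0)
    return zlib.crc32(read_exact(f, end))


def build_index(binary_path, index_path=None) -> str:
    """Scan a binary file and write its index sidecar; returns the path.

    Deterministic: re-running on an unchanged data file produces a
    byte-identical sidecar.
    """
    index_path = index_path or index_path_for(binary_path)
    entries: list[IndexEntry] = []
    seen: set[str] = set()
    with open(binary_path, "rb") as f:
        header, _ = binary_io.read_header(f)
        for offset, blob in binary_io.iter_framed(f):
            raw = record_decompress(blob, header.record_codec)
            (rid_len,) = _U16.unpack_from(raw, 0)
            rid = raw[2:2 + rid_len].decode("ascii")
            if rid in seen:
                raise DuplicateReadIDError(
                    f"duplicate read ID {rid!r} at offset {offset}")
            seen.add(rid)
            entries.append(IndexEntry(rid, offset, 4 + len(blob)))
        f.seek(0, 2)
        size = f.tell()
        crc = _prologue_crc(f)

    body = [_U64.pack(size), _U32.pack(crc), _U64.pack(len(entries))]
    for e in entries:
        rid = e.read_id.encode("ascii")
        body.append(_U16.pack(len(rid)) + rid + _U64.pack(e.offset)
                    + _U32.pack(e.length))
    payload = zlib.compress(b"".join(body), 6)
    with open(index_path, "wb") as out:
        out.write(INDEX_MAGIC)
        out.write(payload)
    return index_path


def load_index(index_path) -> Index:
    with open(index_path, "rb") as f:
        magic = read_exact(f, len(INDEX_MAGIC))
        if magic != INDEX_MAGIC:
            raise CorruptionError(f"bad index magic {magic!r}")
        body = zlib.decompress(f.read())
    (size,) = _U64.unpack_from(body, 0)
    (crc,) = _U32.unpack_from(body, 8)
    (count,) = _U64.unpack_from(body, 12)
    off = 20
    entries: dict[str, tuple[int, int]] = {}
    prev = -1
    for _ in range(count):
        (rid_len,) = _U16.unpack_from(body, off)
        off += 2
        rid = body[off:off + rid_len].decode("ascii")
        off += rid_len
        (rec_off,) = _U64.unpack_from(body, off)
        off += 8
        (rec_len,) = _U32.unpack_from(body, off)
        off += 4
        if rec_off <= prev:
            raise CorruptionError("index offsets are not strictly increasing")
        prev = rec_off
        entries[rid] = (rec_off, rec_len)
    if len(entries) != count:
        raise CorruptionError("index contains duplicate read IDs")
    return Index(data_file_size=size, header_crc=crc, entries=entries)


def verify_index(binary_path, index: Index) -> None:
    with open(binary_path, "rb") as f:
        f.seek(0, 2)
        if f.tell() != index.data_file_size:
            raise StaleIndexError(
                f"{binary_path}: size changed since the index was built")
        if _prologue_crc(f) != index.header_crc:
            raise StaleIndexError(
                f"{binary_path}: header changed since the index was built")


@dataclass
class FetchStats:
    seeks: int
    reads: int
    bytes_read: int


def fetch(binary_path, index: Index, read_ids, on_missing: str = "error",
          return_stats: bool = False):
    """Retrieve records by ID, in request order, one seek per record.

    ``on_missing`` is ``"error"`` (raise naming the ID) or ``"skip"``
    (drop it). Duplicate IDs in the request are fetched per occurrence.
    """
    verify_index(binary_path, index)
    records: list[ReadRecord] = []
    with open(binary_path, "rb") as rawf:
        header, _ = binary_io.read_header(rawf)
        f = CountingFile(rawf)
        for rid in read_ids:
            loc = index.entries.get(rid)
            if loc is None:
                if on_missing == "skip":
                    continue
                raise ReadNotFoundError(f"read ID {rid!r} not in index")
            offset, length = loc
            f.seek(offset)
            buf = f.read(length)
            if len(buf) != length:
                raise CorruptionError(f"short read fetching {rid!r}")
            (rec_len,) = _U32.unpack_from(buf, 0)
            if rec_len != length - 4:
                raise CorruptionError(f"framing mismatch fetching {rid!r}")
            raw = record_decompress(buf[4:], header.record_codec)
            records.append(binary_io.decode_record(raw, header.signal_codec))
        stats = FetchStats(seeks=f.seeks, reads=f.reads, bytes_read=f.bytes_read)
    if return_stats:
        return records, stats
    return records
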