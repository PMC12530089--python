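"""Tab-delimited ASCII dialect (``.slow5``).

One data row per read, with every element of the read stored contiguously in
that row; signal samples are comma-joined inside a single field. The header
grammar is::

    #slow5_version <x.y.z>
    #num_read_groups <n>
    @<key>\\t<value_group0>[\\t<value_group1>...]
    #read_id\\tread_group\\t...<column schema line>

Floats are serialized with Python's shortest round-trip representation, so an
ASCII round trip preserves every field bit-for-bit. A missing value
(``median_before`` absent) is written as the sentinel ``.``. Unknown extra
columns are carried through as opaque text.
"""

from __future__ import annotations

import contextlib
import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import IntegrityError, ParseError, SerializationError
from .model import AUX_FIELDS, PRIMARY_FIELDS, FileHeader, ReadRecord

MISSING = "."
COLUMNS = PRIMARY_FIELDS + AUX_FIELDS


@dataclass
class WriteSummary:
    records: int
    bytes: int = 0


def _fmt_float(x: float) -> str:
    if math.isnan(x):
        return MISSING
    return repr(float(x))


def _parse_float(s: str) -> float:
    if s == MISSING:
        return math.nan
    return float(s)


def _check_text(value: str, what: str) -> str:
    if "\t" in value or "\n" in value or "\r" in value:
        raise SerializationError(f"{what} contains tab/newline: {value!r}")
    return value


@contextlib.contextmanager
def _open_text(target, mode: str):
    if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
        f = open(target, mode, encoding="ascii", newline="")
        try:
            yield f
        finally:
            f.close()
    else:
        yield target


def format_record(rec: ReadRecord, extra_columns: tuple[str, ...] = ()) -> str:
    sig = rec.raw_signal
    fields = [
        _check_text(rec.read_id, "read_id"),
        str(rec.read_group),
        _fmt_float(rec.digitisation),
        _fmt_float(rec.offset),
        _fmt_float(rec.range),
        _fmt_float(rec.sampling_rate),
        str(rec.len_raw_signal),
        ",".join(map(str, sig.tolist())),
        _check_text(rec.channel_number, "channel_number"),
        _fmt_float(rec.median_before),
        str(rec.read_number),
        str(rec.start_mux),
        str(rec.start_time),
    ]
    for col in extra_columns:
        fields.append(_check_text(rec.extras.get(col, MISSING), f"extra field {col}"))
    return "\t".join(fields)


def write_ascii(header: FileHeader, reads: Iterable[ReadRecord], sink,
                extra_columns: tuple[str, ...] | None = None) -> WriteSummary:
    """Write header and records to ``sink`` (path or text file object).

    ``extra_columns`` names the opaque auxiliary columns to emit; when None
    they are taken from the first record's extras (sorted).
    """
    header.validate()
    reads = iter(reads)
    first = next(reads, None)
    if extra_columns is None:
        extra_columns = tuple(sorted(first.extras)) if first is not None else ()

    with _open_text(sink, "w") as f:
        ver = ".".join(map(str, header.version))
        f.write(f"#slow5_version\t{ver}\n")
        f.write(f"#num_read_groups\t{header.num_read_groups}\n")
        for key, values in header.attributes.items():
            _check_text(key, "attribute key")
            for v in values:
                _check_text(v, f"attribute {key}")
            f.write("@" + key + "\t" + "\t".join(values) + "\n")
        f.write("#" + "\t".join(COLUMNS + extra_columns) + "\n")
        n = 0
        for rec in ([first] if first is not None else []):
            n += _write_row(f, rec, header, extra_columns)
        for rec in reads:
            n += _write_row(f, rec, header, extra_columns)
    return WriteSummary(records=n)


def _write_row(f, rec: ReadRecord, header: FileHeader,
               extra_columns: tuple[str, ...]) -> int:
    rec.validate()
    if rec.read_group >= header.num_read_groups:
        raise SerializationError(
            f"read {rec.read_id!r}: read_group {rec.read_group} >= "
            f"num_read_groups {header.num_read_groups}"
        )
    f.write(format_record(rec, extra_columns) + "\n")
    return 1


def _parse_version(token: str) -> tuple[int, int, int]:
    parts = token.split(".")
    if len(parts) != 3:
        raise ParseError(f"bad version {token!r}", line=1)
    return tuple(int(p) for p in parts)  # type: ignore[return-value]


def read_ascii(source) -> tuple[FileHeader, Iterator[ReadRecord]]:
    """Parse a ``.slow5`` file; records are yielded lazily in file order."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        f: io.TextIOBase = open(source, "r", encoding="ascii", newline="")
        owns = True
    else:
        f, owns = source, False

    line = f.readline()
    lineno = 1
    if not line.startswith("#slow5_version\t"):
        if owns:
            f.close()
        raise ParseError("file does not begin with a #slow5_version line", line=1)
    version = _parse_version(line.rstrip("\n").split("\t", 1)[1])

    header = FileHeader(version=version)
    columns: list[str] | None = None
    while True:
        line = f.readline()
        lineno += 1
        if not line:
            if owns:
                f.close()
            raise ParseError("header ended before the column schema line",
                             line=lineno)
        line = line.rstrip("\n")
        if line.startswith("#num_read_groups\t"):
            header.num_read_groups = int(line.split("\t", 1)[1])
        elif line.startswith("@"):
            key, *values = line[1:].split("\t")
            if len(values) != header.num_read_groups:
                if owns:
                    f.close()
                raise ParseError(
                    f"attribute {key!r} has {len(values)} values for "
                    f"{header.num_read_groups} read groups", line=lineno)
            header.attributes[key] = values
        elif line.startswith("#"):
            columns = line[1:].split("\t")
            break
        else:
            if owns:
                f.close()
            raise ParseError(f"unexpected header line {line!r}", line=lineno)

    if tuple(columns[: len(COLUMNS)]) != COLUMNS:
        if owns:
            f.close()
        raise ParseError("column schema does not begin with the required columns",
                         line=lineno)
    extra_columns = tuple(columns[len(COLUMNS):])

    def _records() -> Iterator[ReadRecord]:
        ln = lineno
        try:
            for line in f:
                ln += 1
                row = line.rstrip("\n").split("\t")
                if len(row) != len(columns):
                    raise ParseError(
                        f"expected {len(columns)} columns, got {len(row)}", line=ln)
                yield _parse_row(row, extra_columns, ln)
        finally:
            if owns:
                f.close()

    return header, _records()


def _parse_row(row: list[str], extra_columns: tuple[str, ...],
               lineno: int) -> ReadRecord:
    declared_len = int(row[6])
    sig_text = row[7]
    if sig_text:
        try:
            sig = np.fromiter((int(t) for t in sig_text.split(",")),
                              dtype=np.int16)
        except ValueError as e:
            raise ParseError(f"bad signal value: {e}", line=lineno) from e
    else:
        sig = np.zeros(0, dtype=np.int16)
    if declared_len != sig.size:
        raise IntegrityError(
            f"line {lineno}: len_raw_signal={declared_len} but signal has "
            f"{sig.size} values"
        )
    return ReadRecord(
        read_id=row[0],
        read_group=int(row[1]),
        digitisation=_parse_float(row[2]),
        offset=_parse_float(row[3]),
        range=_parse_float(row[4]),
        sampling_rate=_parse_float(row[5]),
        raw_signal=sig,
        channel_number=row[8],
        median_before=_parse_float(row[9]),
        read_number=int(row[10]),
        start_mux=int(row[11]),
        start_time=int(row[12]),
        extras=dict(zip(extra_columns, row[len(COLUMNS):])),
    )
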