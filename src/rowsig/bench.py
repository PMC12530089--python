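"""Read-benchmark harness.

Reproduces the three-step benchmark protocol used for raw-signal file
formats: (1) load a batch of reads from disk, decompress and parse them —
this phase is timed; (2) sum each read's signal values as a stand-in for a
consuming workload such as basecalling; (3) emit the sums with metadata so
nothing is optimized away and correctness can be checked across formats.

Field access follows the basecaller-style order (id, signal, sampling rate,
channel, scale, read number, start time, mux) and applies the matching type
conversions — sampling_rate narrowed to uint16, channel_number parsed from
text to uint16, scale computed as range/digitisation — so the conversion cost
a consumer would pay is included in the timed phase.

The *checksum* is a digest over the per-read results; it must be identical
across container formats, worker counts, batch sizes and codecs, which is the
correctness surface these benchmarks assert (wall-clock numbers are reported,
never asserted — they are hardware-bound).
"""

from __future__ import annotations

import hashlib
import json
import resource
import time
from dataclasses import dataclass, field

import numpy as np

from . import binary_io, columnar
from .errors import ConfigError, ConversionError
from .index import build_index, fetch, index_path_for, load_index

_U16_MAX = 0xFFFF


@dataclass
class BenchEntry:
    """Per-read output of the consuming workload (step 2/3)."""

    read_id: str
    signal_sum: int
    sampling_rate_u16: int
    channel_u16: int
    scale: float
    read_number: int
    start_time: int
    start_mux: int

    def key(self) -> str:
        return (f"{self.read_id}\t{self.signal_sum}\t{self.sampling_rate_u16}"
                f"\t{self.channel_u16}\t{self.scale:.17g}\t{self.read_number}"
                f"\t{self.start_time}\t{self.start_mux}")


@dataclass
class BenchReport:
    phase1_seconds: float
    records: int
    batches: int
    checksum: str
    peak_mem_bytes: int
    seeks: int
    config: dict = field(default_factory=dict)
    entries: list[BenchEntry] | None = None  # kept in memory, not serialized

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "entries"}
        return json.dumps(d, indent=2, sort_keys=True)


def digest(entries) -> str:
    """Order-independent digest of per-read results (multiset semantics)."""
    h = hashlib.sha256()
    for key in sorted(e.key() for e in entries):
        h.update(key.encode())
        h.update(b"\n")
    return h.hexdigest()


def peak_mem_bytes() -> int:
    """Peak RSS of this process via OS resource accounting (kiB on Linux)."""
    return resource.getrusage(resource.RUSAGE_SELF).ru_maxrss * 1024


def consume_record(rec) -> BenchEntry:
    """Basecaller-order field access with narrowing type conversions."""
    rid = rec.read_id
    signal_sum = int(np.sum(rec.raw_signal, dtype=np.int64))
    sr = rec.sampling_rate
    if not (0 <= sr <= _U16_MAX):
        raise ConversionError(
            f"read {rid!r}: sampling_rate {sr} does not fit uint16")
    sr16 = int(sr)
    try:
        ch = int(rec.channel_number)
    except ValueError as e:
        raise ConversionError(
            f"read {rid!r}: channel_number {rec.channel_number!r} is not "
            f"numeric") from e
    if not (0 <= ch <= _U16_MAX):
        raise ConversionError(
            f"read {rid!r}: channel_number {ch} does not fit uint16")
    scale = rec.range / rec.digitisation
    return BenchEntry(rid, signal_sum, sr16, ch, scale,
                      rec.read_number, rec.start_time, rec.start_mux)


def bench_sequential(path, fmt: str = "blow5", n_workers: int = 1,
                     batch_size: int = 1000) -> BenchReport:
    """Timed sequential scan of a container file."""
    entries: list[BenchEntry] = []
    phase1 = 0.0
    batches = 0

    if fmt == "blow5":
        t0 = time.perf_counter()
        stream = binary_io.parallel_decode(path, batch_size=batch_size,
                                           n_workers=n_workers)
        pending: list = []
        while True:
            t0 = time.perf_counter()
            rec = next(stream, None)
            phase1 += time.perf_counter() - t0
            if rec is None:
                break
            pending.append(rec)
            if len(pending) == batch_size:
                batches += 1
                entries.extend(consume_record(r) for r in pending)
                pending = []
        if pending:
            batches += 1
            entries.extend(consume_record(r) for r in pending)
    elif fmt == "colsig":
        t0 = time.perf_counter()
        _, stream = columnar.read_columnar(path)
        phase1 += time.perf_counter() - t0
        pending = []
        while True:
            t0 = time.perf_counter()
            rec = next(stream, None)
            phase1 += time.perf_counter() - t0
            if rec is None:
                break
            pending.append(rec)
            if len(pending) == batch_size:
                batches += 1
                entries.extend(consume_record(r) for r in pending)
                pending = []
        if pending:
            batches += 1
            entries.extend(consume_record(r) for r in pending)
    else:
        raise ConfigError(f"unknown format {fmt!r}")

    return BenchReport(
        phase1_seconds=phase1, records=len(entries), batches=batches,
        checksum=digest(entries), peak_mem_bytes=peak_mem_bytes(), seeks=0,
        config={"mode": "sequential", "format": fmt, "n_workers": n_workers,
                "batch_size": batch_size, "path": str(path)},
        entries=entries,
    )


def bench_random(path, id_list_path, fmt: str = "blow5") -> BenchReport:
    """Timed random access: index fetch (blow5) or walker (colsig)."""
    with open(id_list_path) as f:
        ids = [line.strip() for line in f if line.strip()]

    t0 = time.perf_counter()
    if fmt == "blow5":
        idx_path = index_path_for(path)
        import os
        if not os.path.exists(idx_path):
            build_index(path)
        idx = load_index(idx_path)
        records, stats = fetch(path, idx, ids, return_stats=True)
        seeks = stats.seeks
    elif fmt == "colsig":
        records, wstats = columnar.walker_fetch(path, ids, return_stats=True)
        seeks = wstats.seeks
    else:
        raise ConfigError(f"unknown format {fmt!r}")
    phase1 = time.perf_counter() - t0

    entries = [consume_record(r) for r in records]
    return BenchReport(
        phase1_seconds=phase1, records=len(entries), batches=1,
        checksum=digest(entries), peak_mem_bytes=peak_mem_bytes(),
        seeks=seeks,
        config={"mode": "random", "format": fmt, "ids": str(id_list_path),
                "n_ids": len(ids), "path": str(path)},
        entries=entries,
    )


def sample_ids(path, k: int, seed: int, out_path) -> list[str]:
    """Uniform without-replacement ID sample from a binary file.

    Uses the index sidecar when present (building it otherwise), writes one
    ID per line, and is deterministic for a given seed.
    """
    import os
    idx_path = index_path_for(path)
    if not os.path.exists(idx_path):
        build_index(path)
    idx = load_index(idx_path)
    all_ids = list(idx.entries.keys())
    if k > len(all_ids):
        raise ConfigError(f"k={k} exceeds record count {len(all_ids)}")
    rng = np.random.default_rng(seed)
    chosen = [all_ids[i] for i in rng.choice(len(all_ids), size=k,
                                             replace=False)]
    with open(out_path, "w") as f:
        for rid in chosen:
            f.write(rid + "\n")
    return chosen
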