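"""Acquisition simulator: real-time row-format writing with 2-pass files.

Models a nanopore instrument attached to this computer. The device has
``n_positions`` sequencing positions (flow cells) of ``channels_per_position``
channels each; every active channel produces ``sampling_rate`` samples per
second, delivered to software in chunks of ``chunk_size`` samples (so one
acquisition tick lasts ``chunk_size / sampling_rate`` seconds).

Because a row-based container stores each read contiguously, a read cannot
be laid onto the final file until it is complete. Writing is therefore
split by read length:

* reads no longer than one chunk (*direct*) are buffered in RAM and appended
  whole to a per-position direct output file on completion;
* longer reads (*two-pass*) stream each acquired chunk to a per-read
  temporary file; on completion a merge worker reads the temporary file
  back, appends the whole read to a separate per-position merged output
  file, and deletes the temporary.

Three worker pools run per position per tick — acquisition, merge, and
read-back (which re-reads completed records to mimic live basecalling). A
pool task that takes longer than its real-time deadline raises a *warning*;
capacity search increases ``n_positions`` until warnings appear, treating a
single warning as failure.

The wall-clock deadline for every task is ``chunk_interval * time_dilation``
seconds. ``time_dilation`` is the wall-time budget allowed per simulated
second: 1 reproduces real-time strictness, larger values relax deadlines so
desk-scale runs can cover long simulated durations without idling, and 0
makes every deadline impossible.
"""

from __future__ import annotations

import math
import os
import shutil
import tempfile
import time
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .binary_io import BinaryWriter, decode_record, iter_framed, read_header
from .codec import record_decompress
from .errors import ConfigError, RunDirError
from .model import FileHeader, ReadRecord

GIB = 2**30

DIRECT = "direct"
TWO_PASS = "two_pass"

POOLS = ("acquisition", "merge", "readback")


def classify_read(length_samples: int, chunk_size: int) -> str:
    """Route a read by length: at most one chunk goes direct, longer goes
    through 2-pass writing. Boundary reads (length == chunk_size) fit one
    chunk buffer and go direct."""
    if length_samples < 1:
        raise ConfigError("read length must be >= 1")
    return DIRECT if length_samples <= chunk_size else TWO_PASS


def memory_budget(n_channels: int, chunk_size: int,
                  bytes_per_sample: int) -> float:
    """RAM (GiB) to hold one chunk buffer per channel."""
    if n_channels <= 0 or chunk_size <= 0 or bytes_per_sample <= 0:
        raise ConfigError("memory_budget arguments must be positive")
    return n_channels * chunk_size * bytes_per_sample / GIB


def chunk_to_bases(chunk_size: int, sampling_rate: float,
                   translocation_bps: float) -> float:
    """Bases traversing the pore during one chunk of samples."""
    if sampling_rate <= 0 or translocation_bps <= 0:
        raise ConfigError("rates must be positive")
    return chunk_size / sampling_rate * translocation_bps


@dataclass
class SimConfig:
    """Acquisition-simulation parameters.

    Defaults model a single PromethION-class position: 3,000 channels,
    5 kHz sampling, 400 bases/s translocation, 200,000-sample chunks of
    2-byte samples. ``occupancy`` is the fraction of channels actively
    producing signal (pore duty cycle); ``throttle`` optionally injects
    deterministic extra task latency (seconds) for capacity testing.
    """

    n_positions: int = 1
    channels_per_position: int = 3000
    sampling_rate: float = 5000.0
    translocation_bps: float = 400.0
    chunk_size: int = 200_000
    bytes_per_sample: int = 2
    duration_s: float = 60.0
    occupancy: float = 0.45
    read_length_median: float = 8000.0
    read_length_sigma: float = 1.0
    read_length_min: int = 100
    read_length_max: int = 2_000_000
    seed: int = 0
    time_dilation: float = 1.0
    throttle: Callable[[int, str, int], float] | None = None

    @property
    def chunk_interval_s(self) -> float:
        return self.chunk_size / self.sampling_rate

    @property
    def total_channels(self) -> int:
        return self.n_positions * self.channels_per_position

    @property
    def active_channels_per_position(self) -> int:
        return max(1, round(self.occupancy * self.channels_per_position))

    def validate(self) -> None:
        if self.n_positions < 1:
            raise ConfigError("n_positions must be >= 1")
        if self.channels_per_position < 1:
            raise ConfigError("channels_per_position must be >= 1")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive (zero-length run)")
        if self.chunk_size < 1:
            raise ConfigError("chunk_size must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not (0 < self.occupancy <= 1):
            raise ConfigError("occupancy must be in (0, 1]")
        if self.time_dilation < 0:
            raise ConfigError("time_dilation must be >= 0")
        if self.read_length_min > self.read_length_max:
            raise ConfigError("read_length_min > read_length_max")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class PoolStats:
    tasks: int = 0
    misses: int = 0
    total_s: float = 0.0
    max_s: float = 0.0

    def record(self, wall: float, deadline: float) -> None:
        self.tasks += 1
        self.total_s += wall
        self.max_s = max(self.max_s, wall)
        if wall > deadline:
            self.misses += 1

    @property
    def mean_s(self) -> float:
        return self.total_s / self.tasks if self.tasks else 0.0


@dataclass
class SimReport:
    warnings: int
    reads_completed: int
    samples_written: int
    bytes_written: int
    ram_peak_estimate_bytes: int
    temp_files_remaining: int
    duration_s: float
    generated_completed_samples: int
    reads_direct: int
    reads_two_pass: int
    reads_read_back: int
    pool_stats: dict[str, PoolStats] = field(default_factory=dict)

    def table_row(self) -> dict[str, float]:
        """Throughput summary in instrument-benchmark units."""
        hours = self.duration_s / 3600.0
        return {
            "file_size_per_hour_gib": self.bytes_written / GIB / hours,
            "ram_gib": self.ram_peak_estimate_bytes / GIB,
            "reads_millions": self.reads_completed / 1e6,
            "samples_billions": self.samples_written / 1e9,
        }

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "pool_stats"}
        d["pool_stats"] = {
            name: {"tasks": s.tasks, "misses": s.misses,
                   "mean_s": s.mean_s, "max_s": s.max_s}
            for name, s in self.pool_stats.items()
        }
        d.update(self.table_row())
        return d


class _Channel:
    """Sample source for one active channel: an endless sequence of reads."""

    __slots__ = ("rng", "cfg", "global_number", "read_number", "sample_clock",
                 "cur_len", "cur_acquired", "cur_meta", "parts", "tmp_file",
                 "tmp_path", "route")

    def __init__(self, cfg: SimConfig, position: int, chan: int):
        self.rng = np.random.default_rng(
            (cfg.seed & 0x7FFFFFFF, position, chan))
        self.cfg = cfg
        self.global_number = position * cfg.channels_per_position + chan + 1
        self.read_number = 0
        self.sample_clock = 0
        self.cur_len = 0
        self.cur_acquired = 0
        self.cur_meta: dict | None = None
        self.parts: list[np.ndarray] = []
        self.tmp_file = None
        self.tmp_path = None
        self.route = DIRECT

    def _start_read(self, tmp_dir: str) -> None:
        cfg = self.cfg
        n = int(np.clip(round(self.rng.lognormal(
            math.log(cfg.read_length_median), cfg.read_length_sigma)),
            cfg.read_length_min, cfg.read_length_max))
        self.cur_len = n
        self.cur_acquired = 0
        self.route = classify_read(n, cfg.chunk_size)
        self.cur_meta = {
            "read_number": self.read_number,
            "start_time": self.sample_clock,
            "start_mux": int(self.rng.integers(1, 5)),
        }
        self.read_number += 1
        self.parts = []
        if self.route == TWO_PASS:
            self.tmp_path = os.path.join(
                tmp_dir, f"ch{self.global_number}_r{self.cur_meta['read_number']}.tmp")
            self.tmp_file = open(self.tmp_path, "wb")

    def acquire_tick(self, tmp_dir: str):
        """Produce one chunk interval of samples; yield completed reads as
        (record, tmp_path_or_None, length)."""
        cfg = self.cfg
        budget = cfg.chunk_size
        completed = []
        while budget > 0:
            if self.cur_meta is None:
                self._start_read(tmp_dir)
            take = min(budget, self.cur_len - self.cur_acquired)
            samples = self.rng.integers(350, 750, size=take, dtype=np.int16)
            if self.route == DIRECT:
                self.parts.append(samples)
            else:
                self.tmp_file.write(samples.astype("<i2").tobytes())
            self.cur_acquired += take
            self.sample_clock += take
            budget -= take
            if self.cur_acquired == self.cur_len:
                completed.append(self._finish_read())
        return completed

    def _finish_read(self):
        meta = self.cur_meta
        length = self.cur_len
        if self.route == DIRECT:
            signal = np.concatenate(self.parts) if self.parts else \
                np.zeros(0, np.int16)
            rec = self._record(signal, meta)
            out = (rec, None, length)
        else:
            self.tmp_file.close()
            rec = self._record(None, meta)
            out = (rec, self.tmp_path, length)
            self.tmp_file = None
            self.tmp_path = None
        self.cur_meta = None
        self.parts = []
        return out

    def _record(self, signal, meta) -> ReadRecord:
        cfg = self.cfg
        return ReadRecord(
            read_id=f"sim-c{self.global_number}-r{meta['read_number']}",
            read_group=0,
            digitisation=8192.0,
            offset=0.0,
            range=1467.61,
            sampling_rate=cfg.sampling_rate,
            raw_signal=signal if signal is not None else np.zeros(0, np.int16),
            channel_number=str(self.global_number),
            median_before=float("nan"),
            read_number=meta["read_number"],
            start_mux=meta["start_mux"],
            start_time=meta["start_time"],
        )

    def abandon(self) -> None:
        """Drop an in-progress read at shutdown (its data never counted)."""
        if self.tmp_file is not None:
            self.tmp_file.close()
            os.unlink(self.tmp_path)
            self.tmp_file = None
            self.tmp_path = None
        self.cur_meta = None
        self.parts = []


def _prepare_outdir(outdir) -> str:
    outdir = os.fspath(outdir)
    if os.path.exists(outdir):
        leftovers = [n for n in os.listdir(outdir)
                     if n.endswith((".blow5", ".tmp")) or n == "tmp"]
        if leftovers:
            raise RunDirError(
                f"{outdir} contains output from a previous run "
                f"({leftovers[:3]}...); refusing to overwrite")
    else:
        os.makedirs(outdir)
    os.makedirs(os.path.join(outdir, "tmp"), exist_ok=True)
    return outdir


def run_simulation(cfg: SimConfig, outdir) -> SimReport:
    """Run the acquisition simulation; see the module docstring.

    Produces, per position, ``pos<i>_direct.blow5`` (short reads) and
    ``pos<i>_merged.blow5`` (2-pass reads), each a valid finalized row-format
    file. Every completed read appears contiguously in exactly one output.
    """
    cfg.validate()
    outdir = _prepare_outdir(outdir)
    tmp_dir = os.path.join(outdir, "tmp")
    interval = cfg.chunk_interval_s
    deadline = interval * cfg.time_dilation
    n_ticks = math.ceil(cfg.duration_s / interval)

    header = FileHeader(attributes={"run_id": [f"acq-sim-{cfg.seed}"]})
    positions = []
    for p in range(cfg.n_positions):
        chans = [_Channel(cfg, p, c)
                 for c in range(cfg.active_channels_per_position)]
        direct_w = BinaryWriter(os.path.join(outdir, f"pos{p}_direct.blow5"),
                                header)
        merged_w = BinaryWriter(os.path.join(outdir, f"pos{p}_merged.blow5"),
                                header)
        positions.append({
            "channels": chans, "direct": direct_w, "merged": merged_w,
            "pending_merge": [], "readback_offsets": {}, "files": {},
        })

    pool_stats = {name: PoolStats() for name in POOLS}
    warnings = 0
    reads_completed = 0
    reads_direct = 0
    reads_two_pass = 0
    samples_written = 0
    generated_completed = 0
    reads_read_back = 0

    def throttle_extra(pool: str, position: int) -> float:
        if cfg.throttle is None:
            return 0.0
        return cfg.throttle(cfg.n_positions, pool, position)

    for _tick in range(n_ticks):
        for p, state in enumerate(positions):
            # --- acquisition pool -----------------------------------------
            t0 = time.perf_counter()
            for ch in state["channels"]:
                for rec, tmp_path, length in ch.acquire_tick(tmp_dir):
                    generated_completed += length
                    if tmp_path is None:
                        state["direct"].write(rec)
                        samples_written += length
                        reads_completed += 1
                        reads_direct += 1
                    else:
                        state["pending_merge"].append((rec, tmp_path, length))
            wall = time.perf_counter() - t0 + throttle_extra("acquisition", p)
            pool_stats["acquisition"].record(wall, deadline)
            if wall > deadline:
                warnings += 1

            # --- merge pool -----------------------------------------------
            t0 = time.perf_counter()
            for rec, tmp_path, length in state["pending_merge"]:
                with open(tmp_path, "rb") as tf:
                    signal = np.frombuffer(tf.read(), dtype="<i2")
                rec.raw_signal = signal.astype(np.int16)
                state["merged"].write(rec)
                os.unlink(tmp_path)
                samples_written += length
                reads_completed += 1
                reads_two_pass += 1
            state["pending_merge"] = []
            wall = time.perf_counter() - t0 + throttle_extra("merge", p)
            pool_stats["merge"].record(wall, deadline)
            if wall > deadline:
                warnings += 1

            # --- read-back pool -------------------------------------------
            t0 = time.perf_counter()
            for role in ("direct", "merged"):
                w = state[role]
                w.flush()
                path = os.path.join(outdir, f"pos{p}_{role}.blow5")
                start = state["readback_offsets"].get(role)
                with open(path, "rb") as rf:
                    if start is None:
                        _, start = read_header(rf)
                    rf.seek(start)
                    for _, blob in iter_framed(rf, tolerate_unterminated=True):
                        raw = record_decompress(blob, header.record_codec)
                        decode_record(raw, header.signal_codec)
                        reads_read_back += 1
                    state["readback_offsets"][role] = rf.tell()
            wall = time.perf_counter() - t0 + throttle_extra("readback", p)
            pool_stats["readback"].record(wall, deadline)
            if wall > deadline:
                warnings += 1

    # Shutdown: abandon in-progress reads, finalize outputs.
    bytes_written = 0
    for p, state in enumerate(positions):
        for ch in state["channels"]:
            ch.abandon()
        state["direct"].close()
        state["merged"].close()
        for role in ("direct", "merged"):
            bytes_written += os.path.getsize(
                os.path.join(outdir, f"pos{p}_{role}.blow5"))

    temp_files_remaining = len(os.listdir(tmp_dir))

    return SimReport(
        warnings=warnings,
        reads_completed=reads_completed,
        samples_written=samples_written,
        bytes_written=bytes_written,
        ram_peak_estimate_bytes=int(
            cfg.n_positions * cfg.active_channels_per_position
            * cfg.chunk_size * cfg.bytes_per_sample),
        temp_files_remaining=temp_files_remaining,
        duration_s=n_ticks * interval,
        generated_completed_samples=generated_completed,
        reads_direct=reads_direct,
        reads_two_pass=reads_two_pass,
        reads_read_back=reads_read_back,
        pool_stats=pool_stats,
    )


def capacity_search(base_cfg: SimConfig, position_step: int = 1,
                    max_positions: int = 64, workdir=None,
                    refine: bool = True) -> int:
    """Largest position count that runs with zero warnings.

    Monotone search: start at 1 position, increase by ``position_step`` until
    warnings appear (or ``max_positions`` is reached), then optionally refine
    with unit steps between the last clean and first warning count. A single
    warning is treated as failure; a warning at 1 position reports capacity 0.
    Deterministic whenever the configured throttle is deterministic.
    """
    base_cfg.validate()
    if position_step < 1:
        raise ConfigError("position_step must be >= 1")

    def clean(n: int) -> bool:
        d = tempfile.mkdtemp(prefix=f"capsearch_{n}_", dir=workdir)
        try:
            report = run_simulation(base_cfg.replace(n_positions=n),
                                    os.path.join(d, "out"))
            return report.warnings == 0
        finally:
            shutil.rmtree(d, ignore_errors=True)

    if not clean(1):
        return 0
    last_clean = 1
    n = 1
    while n < max_positions:
        n = min(n + position_step, max_positions)
        if clean(n):
            last_clean = n
        else:
            if refine and position_step > 1:
                for m in range(last_clean + 1, n):
                    if clean(m):
                        last_clean = m
                    else:
                        break
            return last_clean
    return last_clean
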