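"""Seeded synthetic read generator.

Every other module is exercised against reads produced here, so no external
dataset is needed. The generator emulates the *shape* of a nanopore run —
log-normal read lengths, a two-level pore current alternating in short
segments, channel-cycling with per-channel monotone start times — but makes
no attempt at biophysical realism (no squiggle model, no basecallable
structure). Its only job is to produce records whose field types, value
ranges and signal statistics exercise the codecs and containers the way real
data would.

Defaults: log-normal lengths with median 8,000 samples and sigma(log) = 1.0,
clipped to [100, 2,000,000]; signal drawn around two pore levels (ADC counts
450 and 700, sd 20) alternating in 32-sample segments, rounded and clipped to
the signed 16-bit range.

Identical :class:`GenConfig` values yield byte-identical read sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterator

import numpy as np

from .errors import ConfigError
from .model import INT16_MAX, INT16_MIN, FileHeader, ReadRecord

_SEGMENT = 32  # samples per pore-level segment


@dataclass
class GenConfig:
    """Parameters of the synthetic read set."""

    n_reads: int = 100
    seed: int = 0
    length_law: str = "lognormal"
    length_median: float = 8000.0
    length_sigma: float = 1.0
    length_min: int = 100
    length_max: int = 2_000_000
    signal_levels: tuple[float, float] = (450.0, 700.0)
    signal_sd: float = 20.0
    n_channels: int = 512
    digitisation: float = 8192.0
    range: float = 1467.61
    sampling_rate: float = 5000.0
    median_before_missing_rate: float = 0.05

    def validate(self) -> None:
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        if self.length_min > self.length_max:
            raise ConfigError(
                f"length_min {self.length_min} > length_max {self.length_max}"
            )
        if self.length_law != "lognormal":
            raise ConfigError(f"unknown length law {self.length_law!r}")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")

    def replace(self, **kw) -> "GenConfig":
        return replace(self, **kw)

    def to_mapping(self) -> dict[str, str]:
        """Flat key=value form (config files, CLI echo)."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            out[f.name] = str(v)
        return out

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "GenConfig":
        kw = {}
        for f in fields(cls):
            if f.name not in mapping:
                continue
            raw = mapping[f.name]
            if f.name == "signal_levels":
                kw[f.name] = tuple(float(x) for x in raw.split(","))
            elif f.type in ("int", int):
                kw[f.name] = int(raw)
            elif f.type in ("float", float):
                kw[f.name] = float(raw)
            else:
                kw[f.name] = raw
        unknown = set(mapping) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)


def default_header(cfg: GenConfig, record_codec: str = "none",
                   signal_codec: str = "none") -> FileHeader:
    """A one-read-group header matching the generator's run metadata."""
    return FileHeader(
        record_codec=record_codec,
        signal_codec=signal_codec,
        num_read_groups=1,
        attributes={
            "run_id": [f"synthetic-run-{cfg.seed}"],
            "flow_cell_id": ["SYN00001"],
            "sample_frequency": [str(cfg.sampling_rate)],
        },
    )


def generate_lengths(cfg: GenConfig, rng: np.random.Generator) -> np.ndarray:
    lengths = rng.lognormal(math.log(cfg.length_median), cfg.length_sigma,
                            size=cfg.n_reads)
    return np.clip(np.rint(lengths), cfg.length_min, cfg.length_max).astype(np.int64)


def _segment_signal(n: int, levels: tuple[float, float], sd: float,
                    rng: np.random.Generator, phase: int) -> np.ndarray:
    level_idx = ((np.arange(n) // _SEGMENT) + phase) % 2
    base = np.asarray(levels, dtype=np.float64)[level_idx]
    sig = base + rng.normal(0.0, sd, size=n)
    return np.clip(np.rint(sig), INT16_MIN, INT16_MAX).astype(np.int16)


def generate_reads(cfg: GenConfig) -> Iterator[ReadRecord]:
    """Yield exactly ``cfg.n_reads`` deterministic records.

    Read IDs are unique within the set; channel numbers cycle over
    ``1..n_channels``; start times are strictly increasing per channel.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = generate_lengths(cfg, rng)
    offsets = np.rint(rng.uniform(-10.0, 10.0, size=cfg.n_reads))
    muxes = rng.integers(1, 5, size=cfg.n_reads)
    gaps = rng.integers(10, 2000, size=cfg.n_reads)
    mb_missing = rng.random(cfg.n_reads) < cfg.median_before_missing_rate
    mb_values = np.round(rng.uniform(60.0, 120.0, size=cfg.n_reads), 6)

    chan_time = np.zeros(cfg.n_channels, dtype=np.int64)
    chan_count = np.zeros(cfg.n_channels, dtype=np.int64)

    for i in range(cfg.n_reads):
        ch = i % cfg.n_channels
        n = int(lengths[i])
        sig = _segment_signal(n, cfg.signal_levels, cfg.signal_sd, rng, phase=i % 2)
        rec = ReadRecord(
            read_id=f"syn-{cfg.seed:08x}-{i:08d}",
            read_group=0,
            digitisation=cfg.digitisation,
            offset=float(offsets[i]),
            range=cfg.range,
            sampling_rate=cfg.sampling_rate,
            raw_signal=sig,
            channel_number=str(ch + 1),
            median_before=math.nan if mb_missing[i] else float(mb_values[i]),
            read_number=int(chan_count[ch]),
            start_mux=int(muxes[i]),
            start_time=int(chan_time[ch]),
        )
        chan_count[ch] += 1
        chan_time[ch] += n + int(gaps[i])
        yield rec


def generate_read_list(cfg: GenConfig) -> list[ReadRecord]:
    return list(generate_reads(cfg))
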