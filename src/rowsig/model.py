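"""Core domain types for row-based raw nanopore signal storage.

A *read* is one pass of a molecule through a pore: a unique identifier, a set
of run-level calibration values, a handful of acquisition attributes, and the
raw signal itself — a time series of signed 16-bit ADC counts. A *file header*
carries the container version, the codecs used for record and signal payloads,
and per-read-group metadata attributes (one value column per group).

The picoampere conversion used throughout the ecosystem is

    pA[i] = (raw[i] + offset) * range / digitisation

with ``scale = range / digitisation`` being the single multiplier many
downstream consumers precompute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCalibrationError, ValidationError

INT16_MIN = -(2**15)
INT16_MAX = 2**15 - 1

RECORD_CODECS = ("none", "zlib", "zstd")
SIGNAL_CODECS = ("none", "svb32-zd", "svb16-zd")

#: Fixed column order of the primary per-read fields in both dialects.
PRIMARY_FIELDS = (
    "read_id",
    "read_group",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "len_raw_signal",
    "raw_signal",
)

#: Auxiliary fields carried by both dialects, in serialization order.
AUX_FIELDS = (
    "channel_number",
    "median_before",
    "read_number",
    "start_mux",
    "start_time",
)


@dataclass
class ReadRecord:
    """One raw nanopore read.

    ``median_before`` may be absent; absence is represented as NaN in memory,
    serialized as ``.`` in the ASCII dialect and as an IEEE NaN in binary.
    Unknown auxiliary columns encountered on read are preserved verbatim in
    ``extras`` as opaque text so they survive round trips.
    """

    read_id: str
    read_group: int = 0
    digitisation: float = 8192.0
    offset: float = 0.0
    range: float = 1467.61
    sampling_rate: float = 5000.0
    raw_signal: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int16))
    channel_number: str = "1"
    median_before: float = math.nan
    read_number: int = 0
    start_mux: int = 1
    start_time: int = 0
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_signal = np.asarray(self.raw_signal, dtype=np.int16)

    @property
    def len_raw_signal(self) -> int:
        return int(self.raw_signal.shape[0])

    def validate(self) -> None:
        if not self.read_id:
            raise ValidationError("read_id must be non-empty")
        if "\t" in self.read_id or "\n" in self.read_id:
            raise ValidationError(f"read_id contains tab/newline: {self.read_id!r}")
        if self.read_group < 0:
            raise ValidationError("read_group must be non-negative")
        if not (self.digitisation > 0):
            raise InvalidCalibrationError(
                f"digitisation must be positive, got {self.digitisation}"
            )
        if not (1 <= self.start_mux <= 4):
            raise ValidationError(f"start_mux must be in 1..4, got {self.start_mux}")
        if self.raw_signal.dtype != np.int16:
            raise ValidationError("raw_signal must be int16")


@dataclass
class FileHeader:
    """Container-level metadata shared by every record in a file."""

    version: tuple[int, int, int] = (1, 0, 0)
    record_codec: str = "none"
    signal_codec: str = "none"
    num_read_groups: int = 1
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.record_codec not in RECORD_CODECS:
            raise ValidationError(f"unknown record codec {self.record_codec!r}")
        if self.signal_codec not in SIGNAL_CODECS:
            raise ValidationError(f"unknown signal codec {self.signal_codec!r}")
        if self.num_read_groups < 1:
            raise ValidationError("num_read_groups must be >= 1")
        for key, values in self.attributes.items():
            if len(values) != self.num_read_groups:
                raise ValidationError(
                    f"attribute {key!r} has {len(values)} values for "
                    f"{self.num_read_groups} read groups"
                )


def pa_convert(record: ReadRecord) -> np.ndarray:
    """Convert a record's raw ADC counts to picoamperes.

    Returns a float64 array of length ``len_raw_signal`` where element *i* is
    ``(raw_signal[i] + offset) * range / digitisation``.
    """
    if not (record.digitisation > 0):
        raise InvalidCalibrationError(
            f"digitisation must be positive, got {record.digitisation}"
        )
    scale = record.range / record.digitisation
    return (record.raw_signal.astype(np.float64) + record.offset) * scale


def _float_eq(a: float, b: float) -> bool:
    if math.isnan(a) and math.isnan(b):
        return True
    return a == b


def records_equal(a: ReadRecord, b: ReadRecord) -> bool:
    """Field-exact record equality (NaN compares equal to NaN)."""
    return (
        a.read_id == b.read_id
        and a.read_group == b.read_group
        and _float_eq(a.digitisation, b.digitisation)
        and _float_eq(a.offset, b.offset)
        and _float_eq(a.range, b.range)
        and _float_eq(a.sampling_rate, b.sampling_rate)
        and np.array_equal(a.raw_signal, b.raw_signal)
        and a.channel_number == b.channel_number
        and _float_eq(a.median_before, b.median_before)
        and a.read_number == b.read_number
        and a.start_mux == b.start_mux
        and a.start_time == b.start_time
        and a.extras == b.extras
    )
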