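# Methods

This note documents the models, on-disk dialects, numerical choices and
known limitations behind `rowsig`. The dialects here are self-consistent and
fully specified in this repository; they are *not* byte-compatible with any
external tool's container formats, by design — the package studies layout
and access-pattern mechanics, not interchange.

## Containers

**ASCII row format (`.slow5`).** Tab-separated, one read per row, signal
comma-joined in a single field. Header grammar:
`#slow5_version x.y.z`, `#num_read_groups n`, `@key\tvalue_per_group...`,
then one `#`-prefixed column-schema line. The fixed columns are
`read_id, read_group, digitisation, offset, range, sampling_rate,
len_raw_signal, raw_signal, channel_number, median_before, read_number,
start_mux, start_time`; further columns are preserved as opaque text.
Floats are written with Python's shortest round-trip representation
(`repr`), so ASCII round trips are bit-exact; a missing `median_before` is
the sentinel `.` (NaN in memory and in binary). These are package decisions:
the row-format concept constrains neither float precision nor missing-value
encoding.

**Binary row format (`.blow5`).** Little-endian throughout; doubles are
8-byte IEEE-754. Prologue: 8-byte magic, record-codec and signal-codec bytes,
then the (record-codec-compressed) header block. Each record is framed by a
u32 length and is independently decompressible; auxiliary fields travel in a
typed TLV block so unknown fields survive round trips. The end-of-file
marker reuses the impossible frame length `0xFFFFFFFF` plus a 4-byte tag,
which makes "finalized" cheap to verify and makes data appended after
finalization a detectable corruption rather than a silent extension.
The magic/marker constants are arbitrary but fixed.

**Columnar comparator (`.colsig`).** Stores every metadata attribute
contiguously for all reads (fixed-width columns, plus offsets+heap pairs for
the variable-width `read_id`, `channel_number` and `extras` columns) and the
signal as tagged chunks of `chunk_size` samples (default 102,400) that may
interleave between reads. A footer records chunk locations and column
offsets. Two writer policies: `contiguous`, and `round_robin`, which keeps a
window of (default) 4 reads open and cycles one chunk from each —
a deterministic stand-in for the interleaving a live instrument produces,
whose true order depends on unobservable acquisition timing. No per-chunk
compression and no Arrow framing: the comparator isolates the layout
variable, nothing else.

## Signal codec

Pipeline: 16-bit **wraparound deltas** (`d[0] = s[0]`, `d[i] = s[i] - s[i-1]
mod 2^16`, kept in int16), **zigzag map** `z = (d << 1) XOR (d >> 15)`
(non-negative, at most 16 bits — wraparound is what guarantees this bound
and exact invertibility at the int16 extremes), then **stream-variable-byte
packing**: a u64 sample count, control bytes (pad bits zero), then data
bytes, minimal length per value, value 0 still costing 1 byte.
`svb32-zd` uses 2 control bits per value (1–4 byte values, 4 per control
byte); `svb16-zd` uses 1 control bit per value (1–2 byte values, 8 per
control byte), which suffices because zigzag values are 16-bit. Treating the
first sample as a delta from zero keeps a single code path. The
implementation is NumPy-vectorised scalar logic; SIMD equivalence classes,
not speed, are the contract, and byte compatibility with any external VBZ
stream is a non-goal. Record-level compression is zlib (stdlib) or zstd; the
zstd backend is pyarrow's codec API, with the uncompressed length prefixed
so records stay independently decompressible.

Consequence used by tests: when the first value and all deltas lie in
[-64, 63], every zigzag value is below 256, so the `svb16-zd` data region is
exactly one byte per sample.

## Index and walker

The `.blow5.idx` sidecar maps each read ID to the byte offset of its frame
and its framed length (magic + zlib-compressed entry list). Fetch cost is
exactly one seek and one bounded read per requested read; the package counts
seeks explicitly so tests can assert this. The sidecar stores the data
file's size and a CRC of its prologue; any mismatch raises a stale-index
error — silently reading wrong offsets is the failure mode the check
exists to prevent.

The columnar walker has no sidecar: pass 1 traverses every chunk header plus
the footer and ID column to build a lookup table for *all* reads; pass 2
seeks per chunk and per attribute column of each requested read. For k
requested reads the walker therefore always performs strictly more seeks
than the index (k) whenever reads have at least one chunk and one attribute
column — the mechanistic reason chunked columnar layouts lose at random
access regardless of hardware.

## Benchmark harness

Three steps per batch (default batch size 1,000): timed
load+decompress+parse; signal summation as the consuming workload; emission
of sums and metadata. Field access follows basecaller order with the
matching conversions (sampling_rate and channel_number narrowed to uint16 —
overflow is an error — and `scale = range/digitisation`), so conversion cost
lands in the timed phase. The exact upstream access order is not public in
detail; the order used (id, signal, sampling rate, channel, scale, read
number, start time, mux) is documented here and trivially swappable.
Correctness surface: a SHA-256 digest over sorted per-read result tuples,
which must be invariant across container format, worker count, batch size
and codec. Wall-clock and peak-RSS (via `getrusage` maxrss) are reported but
never asserted — they are hardware properties. Dropping the OS page cache
between runs is a manual runbook step (`/proc/sys/vm/drop_caches`, `purge`)
requiring privileges; it is intentionally not code.

Parallel decode keeps all file I/O in one reader thread and fans record
decompression/parsing out to a worker pool, with batches emitted strictly in
file order; under CPython threading this checks ordering semantics rather
than delivering speedup.

## Acquisition simulator

One simulated position has `channels_per_position` channels (default 3,000),
each active channel producing `sampling_rate` samples/s (default 5,000 Hz)
delivered in chunks of `chunk_size` samples (default 200,000, i.e. a 40 s
chunk interval; at 400 bases/s translocation one chunk spans 16 kbases).
Per-channel RAM is one chunk buffer of `bytes_per_sample` (2), giving the
budget `n_channels x chunk_size x bytes_per_sample` — 53.6 GiB for a
144,000-channel instrument.

Reads of at most one chunk go **direct** (RAM buffer, appended whole on
completion); longer reads go **2-pass** (per-read temporary file, merged and
deleted on completion). The boundary case (length exactly one chunk) goes
direct because it fits a single chunk buffer. Three pools run per position
per tick — acquisition, merge, read-back — each writing to or reading from
its own per-position files, so each completed read lands contiguously in
exactly one output and, within a channel, in sequencing order.

**Deadlines.** Each task must finish within
`chunk_interval x time_dilation` wall seconds or a warning is counted.
`time_dilation` is the wall-time budget allowed per simulated second: 1 is
real-time strictness, larger values relax deadlines so a long simulated
duration can run at desk scale without idling, 0 makes every deadline
impossible. The deadline formula itself is a package definition — the
real-time-constraint concept fixes only that such a deadline exists.
Ticks are processed back-to-back (no sleeping); determinism comes from
seeded per-channel RNG streams and, for capacity experiments, an injectable
deterministic throttle that adds synthetic latency as a function of position
count. Capacity search starts at one position, increases by `position_step`
until any warning appears (a single warning is failure), then refines with
unit steps; it is monotone whenever the throttle is.

**Occupancy** defaults to 0.45 (fraction of channels actively producing
signal): real pore duty cycles are well below 1 and the exact figure varies
by run, so it is a configurable parameter, and absolute throughput numbers
are reported, never asserted. Read lengths use the generator's log-normal
law; per-channel signal is uniform int16 noise, which is sufficient because
the simulator stresses scheduling and I/O, not compression.

Shutdown abandons in-progress reads (they never count as completed),
deletes their temporaries, and finalizes every output file. Re-running into
a directory containing previous outputs fails loudly rather than risking
silent double-writes. Invariants checked every run: zero temporary files
remaining, and samples written exactly equal to the completed-read ledger of
the generator (conservation).

## Synthetic data

The generator (`GenConfig`) emulates the *shape* of a run: log-normal read
lengths (default median 8,000 samples, sigma(log) 1.0, clipped to
[100, 2,000,000] — a long-tailed length law typical of genomic runs),
signal alternating between two pore-current levels (ADC 450/700, sd 20) in
32-sample segments, channel-cycling IDs with per-channel monotone start
times, and ~5% missing `median_before`. It is deliberately not a squiggle
model: no basecallable structure, no pore kinetics. Passing tests therefore
demonstrate container/codec/scheduling correctness and seek mechanics, not
biological fidelity, and compression ratios on this synthetic signal need
not match real-run ratios.

## Problem sizes used in tests

Round-trip and digest checks run at 10^3–2x10^4 reads over all nine codec
combinations; codec equivalence runs 10^4 random arrays per variant against
an independent scalar reference; random-access equivalence uses a
1,000,000-read file with 50,000 sampled IDs — reads kept short (log-normal,
median 15 samples, bounds [8, 64]) since record *count*, not read length,
is the variable that exercises index and walker mechanics; simulator checks
use 2 positions x 10 channels with 500-sample chunks over 30 simulated
seconds at time_dilation 50. These sizes are the package's chosen balance of
coverage and iteration speed.

## Known limitations

* No byte-level compatibility with external container formats, and no
  memory-mapped read path (buffered I/O only).
* The walker's pass-1 lookup lives fully in memory; enormous files would
  need an external-memory variant.
* CPython threads limit true parallel decode speedup; the thread model is
  exercised for ordering correctness.
* Simulator throughput ceilings measured on one machine do not transfer to
  another; only the structural invariants (conservation, contiguity,
  deadline accounting, capacity monotonicity) are asserted.
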