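# rowsig

Row-based storage for raw nanopore signal data, with the machinery needed to
study *why* row layouts behave the way they do: lossless signal codecs, a
read-ID index for single-seek random access, a columnar chunk-interleaved
comparator container, a read-benchmark harness, and a real-time acquisition
simulator with 2-pass parallel file writing.

## The problem

A nanopore sequencer measures ionic current as a molecule transits a pore,
producing per-read time series of signed 16-bit ADC counts — tens of millions
of reads, terabytes of signal, per large run. How those reads are laid out on
disk decides how fast they can be read back:

* **Row layout** (this package's `.slow5`/`.blow5` containers): all metadata
  and signal for one read stored contiguously, reads in sequential rows.
  Sequential scans are pure streaming I/O; random access needs one seek per
  read via a sidecar index mapping `read_id -> (byte offset, length)`.
* **Column/chunk layout** (the `.colsig` comparator): each metadata
  attribute stored contiguously for all reads, signal split into fixed-size
  chunks that may interleave between reads. Writing many concurrent reads is
  easy, but retrieving one read costs a seek per chunk *plus* a seek per
  attribute column, and index-free retrieval requires a two-pass "walker"
  that first traverses the whole file to build a lookup table.

Both containers hold identical information — conversion between all three
formats here is lossless and field-exact — so the layout is the only
variable, and the package's benchmark harness measures its consequences
(timings reported; per-read signal-sum digests asserted).

Raw counts convert to picoamperes as
`pA = (raw + offset) x range / digitisation`, with
`scale = range / digitisation`.

Signal compression is zigzag-delta + stream-variable-byte packing in a
4-byte (2 control bits/value) and a compact 2-byte (1 control bit/value)
variant, optionally wrapped in zlib/zstd record compression.

The acquisition simulator models an instrument with `positions x channels`
pores sampling at 5 kHz: short reads (at most one 200,000-sample chunk)
buffer in RAM and append directly to a per-position row file; longer reads
stream chunk-by-chunk to one temporary file per read, then a merge worker
appends the completed read and deletes the temporary (2-pass writing), while
read-back workers re-read completed reads to mimic live basecalling. Any
worker missing its real-time deadline raises a warning; capacity search
grows the position count until warnings appear.

## Worked example

```sh
rowsig gen -o run.blow5 --n-reads 1000 --seed 7 --length-median 500 \
    --length-min 50 --length-max 5000 --signal-codec svb16-zd --record-codec zlib
rowsig index run.blow5
rowsig bench sample-ids run.blow5 -k 200 --seed 1 -o ids.txt
rowsig bench rand run.blow5 --ids ids.txt
```

prints (hashes/timings machine-dependent):

```
records: 200
phase1_seconds: 0.0166
checksum: 08f59fd2703af9d5f3d42239d5ce2dfbcd67469128de5ff718c9cff9a22afe2a
seeks: 200
peak_mem_bytes: 37605376
```

`seeks: 200` is the row-format random-access contract: one seek per
requested read. Packing the same file into the columnar comparator and
repeating the fetch (`rowsig colsig pack run.blow5 -o run.colsig`, then
`rowsig bench rand run.colsig --ids ids.txt --format colsig`) returns the
identical checksum — same records, bit for bit — but 4,006 seeks,
which is the mechanism that makes index-free chunked layouts slow for random
access. `rowsig sim run --positions 2 --channels 50 --chunk-size 2000 \
--duration 30 --time-dilation 50 --outdir simout` runs the acquisition
simulator and reports warnings, reads, samples and file size per hour.

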