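import io

import numpy as np
import pytest

from rowsig import binary_io
from rowsig.errors import (
    CorruptionError,
    SerializationError,
    TruncatedFileError,
    ValidationError,
)
from rowsig.generate import GenConfig, default_header, generate_read_list
from rowsig.model import ReadRecord, records_equal


def write_bytes(header, reads):
    buf = io.BytesIO()
    binary_io.write_binary(header, reads, buf)
    return buf.getvalue()


class TestRoundTrip:
    def test_empty_file_is_prologue_plus_eof(self, small_header):
        data = write_bytes(small_header, [])
        assert data.startswith(binary_io.MAGIC)
        assert data.endswith(binary_io.EOF_MARKER)
        header, records = binary_io.read_binary(io.BytesIO(data))
        assert records == []
        assert header.attributes == small_header.attributes

    @pytest.mark.parametrize("record_codec", ["none", "zlib", "zstd"])
    @pytest.mark.parametrize("signal_codec", ["none", "svb32-zd", "svb16-zd"])
    def test_field_exact_round_trip_all_codecs(self, header_for, small_reads,
                                               record_codec, signal_codec):
        header = header_for(record_codec, signal_codec)
        data = write_bytes(header, small_reads)
        back_header, back = binary_io.read_binary(io.BytesIO(data))
        assert back_header.record_codec == record_codec
        assert back_header.signal_codec == signal_codec
        assert len(back) == len(small_reads)
        assert all(records_equal(a, b) for a, b in zip(small_reads, back))

    def test_extras_survive_binary_round_trip(self, small_header):
        rec = ReadRecord(read_id="r", raw_signal=np.array([1], np.int16),
                         extras={"end_reason": "unblock_mux_change"})
        (back,) = binary_io.read_binary(
            io.BytesIO(write_bytes(small_header, [rec])))[1]
        assert records_equal(back, rec)

    def test_read_group_out_of_range_rejected(self, small_header):
        rec = ReadRecord(read_id="r", read_group=1,
                         raw_signal=np.array([1], np.int16))
        with pytest.raises(SerializationError):
            write_bytes(small_header, [rec])


@pytest.fixture(scope="module")
def file_2500():
    cfg = GenConfig(n_reads=2500, seed=5, length_median=40.0,
                    length_sigma=0.3, length_min=10, length_max=200)
    buf = io.BytesIO()
    binary_io.write_binary(default_header(cfg), generate_read_list(cfg), buf)
    return buf.getvalue()


class TestBatching:
    def test_batch_sizes_1000_1000_500(self, file_2500):
        sizes = [len(b) for b in
                 binary_io.read_binary_sequential(io.BytesIO(file_2500),
                                                  batch_size=1000)]
        assert sizes == [1000, 1000, 500]

    def test_batching_preserves_record_multiset(self, file_2500):
        one = [r.read_id for batch in binary_io.read_binary_sequential(
            io.BytesIO(file_2500), batch_size=1) for r in batch]
        big = [r.read_id for batch in binary_io.read_binary_sequential(
            io.BytesIO(file_2500), batch_size=999) for r in batch]
        assert one == big

    def test_bad_batch_size_rejected(self, file_2500):
        with pytest.raises(ValidationError):
            next(binary_io.read_binary_sequential(io.BytesIO(file_2500),
                                                  batch_size=0))


class TestParallelDecode:
    def test_worker_counts_agree(self, small_header, small_reads):
        data = write_bytes(small_header, small_reads)
        seq = list(binary_io.parallel_decode(io.BytesIO(data), 7, n_workers=1))
        par = list(binary_io.parallel_decode(io.BytesIO(data), 7, n_workers=8))
        assert len(seq) == len(par) == len(small_reads)
        assert all(records_equal(a, b) for a, b in zip(seq, par))

    def test_signal_sums_invariant_across_workers(self, small_header,
                                                  small_reads):
        data = write_bytes(small_header, small_reads)
        sums = []
        for n_workers in (1, 4):
            records = binary_io.parallel_decode(io.BytesIO(data), 16,
                                                n_workers=n_workers)
            sums.append([int(r.raw_signal.sum()) for r in records])
        assert sums[0] == sums[1]


class TestCorruptionHandling:
    def test_missing_eof_marker(self, small_header, small_reads):
        data = write_bytes(small_header, small_reads[:3])
        with pytest.raises(TruncatedFileError):
            binary_io.read_binary(io.BytesIO(data[:-len(binary_io.EOF_MARKER)]))

    def test_trailing_bytes_after_eof_marker(self, small_header, small_reads):
        data = write_bytes(small_header, small_reads[:3])
        with pytest.raises(CorruptionError):
            binary_io.read_binary(io.BytesIO(data + b"\x00"))

    def test_record_length_overrunning_file(self, small_header):
        data = write_bytes(small_header, [])
        prologue = data[:-len(binary_io.EOF_MARKER)]
        bogus = prologue + (10**6).to_bytes(4, "little") + b"xy"
        with pytest.raises(CorruptionError):
            binary_io.read_binary(io.BytesIO(bogus))

    def test_decode_failure_reports_record_index(self, header_for,
                                                 small_reads):
        header = header_for("zlib", "none")
        buf = io.BytesIO()
        with binary_io.BinaryWriter(buf, header) as w:
            w.write(small_reads[0])
            w.write(small_reads[1])
            garbage = b"\xde\xad\xbe\xef" * 4
            buf.write(len(garbage).to_bytes(4, "little") + garbage)
        with pytest.raises(CorruptionError, match="record 2"):
            for batch in binary_io.read_binary_sequential(
                    io.BytesIO(buf.getvalue())):
                pass

    def test_append_after_finalize_detected_on_read(self, tmp_path,
                                                    small_header, small_reads):
        path = tmp_path / "x.blow5"
        binary_io.write_binary(small_header, small_reads[:2], path)
        # naive append without truncating the end marker
        blob = binary_io.encode_record(small_reads[2], "none")
        with open(path, "ab") as f:
            f.write(len(blob).to_bytes(4, "little") + blob)
        with pytest.raises(CorruptionError):
            binary_io.read_binary(path)

    def test_proper_append_reopens_and_refinalizes(self, tmp_path,
                                                   small_header, small_reads):
        path = tmp_path / "x.blow5"
        binary_io.write_binary(small_header, small_reads[:2], path)
        with binary_io.open_binary_append(path) as w:
            w.write(small_reads[2])
        _, back = binary_io.read_binary(path)
        assert [r.read_id for r in back] == [r.read_id for r in small_reads[:3]]


class TestSizeInvariants:
    def test_uncompressed_file_at_least_two_bytes_per_sample(
            self, small_header, small_reads):
        data = write_bytes(small_header, small_reads)
        total_samples = sum(r.len_raw_signal for r in small_reads)
        assert len(data) >= 2 * total_samples
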