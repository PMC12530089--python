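import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rowsig import codec
from rowsig.errors import CodecRangeError, MalformedPayloadError

from _reference import (
    ref_inverse_zigzag_delta,
    ref_svb_decode,
    ref_svb_encode,
    ref_zigzag_delta,
)

int16_arrays = st.lists(st.integers(-32768, 32767), max_size=200).map(
    lambda xs: np.array(xs, dtype=np.int16))


class TestZigzagDelta:
    def test_empty(self):
        assert codec.zigzag_delta([]).size == 0
        assert codec.inverse_zigzag_delta([]).size == 0

    def test_worked_example(self):
        assert codec.zigzag_delta([100, 102, 101]).tolist() == [200, 4, 1]

    @settings(max_examples=200, deadline=None)
    @given(int16_arrays)
    def test_round_trip_identity(self, sig):
        z = codec.zigzag_delta(sig)
        np.testing.assert_array_equal(codec.inverse_zigzag_delta(z), sig)

    @settings(max_examples=100, deadline=None)
    @given(int16_arrays)
    def test_matches_scalar_reference(self, sig):
        assert codec.zigzag_delta(sig).tolist() == ref_zigzag_delta(sig)

    def test_extreme_deltas_wrap_invertibly(self):
        sig = np.array([-32768, 32767, -32768, 0, 32767], dtype=np.int16)
        z = codec.zigzag_delta(sig)
        assert int(z.max()) <= 0xFFFF  # wraparound keeps zigzag 16-bit
        np.testing.assert_array_equal(codec.inverse_zigzag_delta(z), sig)
        assert ref_inverse_zigzag_delta(ref_zigzag_delta(sig)) == sig.tolist()


@pytest.mark.parametrize("variant", [codec.SVB16, codec.SVB32])
class TestStreamVByte:
    def test_empty_is_count_header_only(self, variant):
        payload = codec.svb_encode([], variant)
        assert payload == (0).to_bytes(8, "little")
        assert codec.svb_decode(payload, variant).size == 0

    def test_zeros_occupy_one_byte_each(self, variant):
        payload = codec.svb_encode([0, 0, 0, 0], variant)
        assert codec.svb_decode(payload, variant).tolist() == [0, 0, 0, 0]

    def test_truncation_detected(self, variant):
        payload = codec.svb_encode([200, 4, 1], variant)
        for cut in range(1, len(payload)):
            with pytest.raises(MalformedPayloadError):
                codec.svb_decode(payload[:-cut], variant)

    def test_trailing_bytes_detected(self, variant):
        payload = codec.svb_encode([200, 4, 1], variant)
        with pytest.raises(MalformedPayloadError):
            codec.svb_decode(payload + b"\x00", variant)

    def test_overflow_rejected(self, variant):
        too_big = 1 << (8 * variant.max_bytes_per_value)
        with pytest.raises(CodecRangeError):
            codec.svb_encode([too_big], variant)

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_round_trip_and_reference_equality(self, variant, data):
        limit = (1 << (8 * variant.max_bytes_per_value)) - 1
        values = data.draw(st.lists(st.integers(0, limit), max_size=100))
        payload = codec.svb_encode(values, variant)
        assert payload == ref_svb_encode(values, variant.max_bytes_per_value)
        assert codec.svb_decode(payload, variant).tolist() == values
        assert ref_svb_decode(payload, variant.max_bytes_per_value) == values


class TestSvb16Example:
    def test_small_values_one_control_byte_one_data_byte_each(self):
        payload = codec.svb_encode([200, 4, 1], codec.SVB16)
        count, ctrl, data = payload[:8], payload[8:9], payload[9:]
        assert int.from_bytes(count, "little") == 3
        assert ctrl == b"\x00"  # three 0-bits used, pad bits zero
        assert data == bytes([200, 4, 1])


class TestRecordCompression:
    @pytest.mark.parametrize("rc", ["none", "zlib", "zstd"])
    def test_round_trip(self, rc):
        rng = np.random.default_rng(0)
        for size in (0, 1, 1000):
            blob = rng.integers(0, 256, size=size, dtype=np.uint8).tobytes()
            out = codec.record_decompress(codec.record_compress(blob, rc), rc)
            assert out == blob

    def test_none_is_identity(self):
        assert codec.record_compress(b"abc", "none") == b"abc"

    def test_zlib_garbage_rejected(self):
        with pytest.raises(MalformedPayloadError):
            codec.record_decompress(b"not zlib data", "zlib")


class TestFullSignalPipeline:
    @pytest.mark.parametrize("signal_codec", ["none", "svb32-zd", "svb16-zd"])
    @pytest.mark.parametrize("record_codec", ["none", "zlib", "zstd"])
    def test_identity_for_all_codec_combinations(self, signal_codec,
                                                 record_codec):
        rng = np.random.default_rng(7)
        for size in (0, 1, 17, 500):
            sig = rng.integers(-32768, 32768, size=size).astype(np.int16)
            wire = codec.record_compress(
                codec.compress_signal(sig, signal_codec), record_codec)
            back = codec.decompress_signal(
                codec.record_decompress(wire, record_codec), signal_codec)
            np.testing.assert_array_equal(back, sig)

    def test_low_delta_signals_cost_one_data_byte_per_sample(self):
        # first value and all deltas in [-64, 63] => every zigzag < 256
        rng = np.random.default_rng(3)
        deltas = rng.integers(-64, 64, size=999)
        sig = np.cumsum(np.concatenate([[17], deltas])).astype(np.int16)
        assert np.ptp(sig) < 32768  # construction stays in range
        payload = codec.svb_encode(codec.zigzag_delta(sig), codec.SVB16)
        n = sig.size
        data_bytes = len(payload) - 8 - (n + 7) // 8
        assert data_bytes == n
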