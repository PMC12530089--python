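import pytest

from rowsig.generate import GenConfig, default_header, generate_read_list


@pytest.fixture(scope="session")
def small_cfg():
    return GenConfig(n_reads=60, seed=42, length_median=300.0,
                     length_sigma=0.6, length_min=20, length_max=2000,
                     n_channels=7)


@pytest.fixture(scope="session")
def small_reads(small_cfg):
    return generate_read_list(small_cfg)


@pytest.fixture(scope="session")
def small_header(small_cfg):
    return default_header(small_cfg)


@pytest.fixture()
def header_for(small_cfg):
    def make(record_codec="none", signal_codec="none"):
        return default_header(small_cfg, record_codec, signal_codec)
    return make
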