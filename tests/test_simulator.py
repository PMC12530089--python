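import os

import pytest

from rowsig import binary_io
from rowsig.errors import ConfigError, RunDirError
from rowsig.simulator import (
    DIRECT,
    TWO_PASS,
    SimConfig,
    capacity_search,
    chunk_to_bases,
    classify_read,
    memory_budget,
    run_simulation,
)


def toy_config(**kw):
    base = dict(n_positions=2, channels_per_position=10, occupancy=1.0,
                chunk_size=500, duration_s=30.0, time_dilation=50.0,
                read_length_median=800.0, read_length_sigma=0.8,
                read_length_min=50, read_length_max=5000, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestClassify:
    @pytest.mark.parametrize("length,expected", [
        (199_999, DIRECT),
        (200_000, DIRECT),   # boundary read fits one chunk buffer
        (200_001, TWO_PASS),
    ])
    def test_chunk_threshold_routing(self, length, expected):
        assert classify_read(length, 200_000) == expected


class TestBudgetFormulas:
    def test_promethion_class_memory_budget(self):
        gib = memory_budget(144_000, 200_000, 2)
        assert gib == pytest.approx(53.644, abs=0.001)
        assert round(gib) == 54

    def test_memory_budget_linear_in_channels(self):
        assert memory_budget(2, 100, 2) == 2 * memory_budget(1, 100, 2)

    def test_tiny_budget(self):
        assert memory_budget(1, 1, 1) == 2.0**-30

    def test_chunk_duration_in_bases(self):
        assert chunk_to_bases(200_000, 5000.0, 400.0) == pytest.approx(16_000)
        assert chunk_to_bases(0, 5000.0, 400.0) == 0.0
        assert chunk_to_bases(100, 5000.0, 800.0) == \
            2 * chunk_to_bases(100, 5000.0, 400.0)


@pytest.fixture(scope="module")
def toy_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim") / "out"
    report = run_simulation(toy_config(), outdir)
    return outdir, report


class TestRunSimulation:
    def test_no_warnings_under_generous_deadlines(self, toy_run):
        _, report = toy_run
        assert report.warnings == 0

    def test_sample_conservation(self, toy_run):
        _, report = toy_run
        assert report.samples_written == report.generated_completed_samples
        assert report.reads_completed == \
            report.reads_direct + report.reads_two_pass
        assert report.reads_two_pass > 0 and report.reads_direct > 0

    def test_all_temp_files_removed(self, toy_run):
        outdir, report = toy_run
        assert report.temp_files_remaining == 0
        assert os.listdir(outdir / "tmp") == []

    def test_outputs_are_valid_finalized_files(self, toy_run, small_header):
        outdir, report = toy_run
        total = 0
        seen = set()
        for name in sorted(os.listdir(outdir)):
            if not name.endswith(".blow5"):
                continue
            _, records = binary_io.read_binary(outdir / name)
            for rec in records:
                assert rec.read_id not in seen  # exactly one output each
                seen.add(rec.read_id)
                total += rec.len_raw_signal
                if "direct" in name:
                    assert rec.len_raw_signal <= 500
                else:
                    assert rec.len_raw_signal > 500
        assert total == report.samples_written
        assert len(seen) == report.reads_completed

    def test_merged_reads_ordered_per_channel(self, toy_run):
        outdir, _ = toy_run
        for name in os.listdir(outdir):
            if "merged" not in name:
                continue
            _, records = binary_io.read_binary(outdir / name)
            per_channel = {}
            for rec in records:
                per_channel.setdefault(rec.channel_number, []).append(rec)
            for recs in per_channel.values():
                starts = [r.start_time for r in recs]
                assert starts == sorted(starts)

    def test_readback_covers_every_completed_read(self, toy_run):
        _, report = toy_run
        assert report.reads_read_back == report.reads_completed

    def test_impossible_deadlines_generate_warnings(self, tmp_path):
        report = run_simulation(toy_config(duration_s=1.0, time_dilation=0.0),
                                tmp_path / "out")
        assert report.warnings > 0

    def test_dirty_outdir_fails_loudly(self, tmp_path):
        outdir = tmp_path / "out"
        run_simulation(toy_config(duration_s=1.0), outdir)
        with pytest.raises(RunDirError):
            run_simulation(toy_config(duration_s=1.0), outdir)

    def test_zero_length_run_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            run_simulation(toy_config(duration_s=0.0), tmp_path / "out")


class TestCapacitySearch:
    @staticmethod
    def throttle_above(ceiling):
        def throttle(n_positions, pool, position):
            return 1e9 if n_positions > ceiling else 0.0
        return throttle

    def base(self, **kw):
        return toy_config(channels_per_position=3, duration_s=1.0,
                          **kw)

    def test_returns_injected_ceiling(self, tmp_path):
        cfg = self.base(throttle=self.throttle_above(5))
        assert capacity_search(cfg, position_step=1, max_positions=8,
                               workdir=tmp_path) == 5

    def test_step_then_refine_matches_unit_step(self, tmp_path):
        cfg = self.base(throttle=self.throttle_above(5))
        assert capacity_search(cfg, position_step=3, max_positions=8,
                               workdir=tmp_path) == 5

    def test_warning_at_one_position_reports_zero(self, tmp_path):
        cfg = self.base(throttle=self.throttle_above(0))
        assert capacity_search(cfg, position_step=1, max_positions=4,
                               workdir=tmp_path) == 0

    def test_monotone_under_deterministic_throttle(self, tmp_path):
        cfg = self.base(throttle=self.throttle_above(3))
        for n in (1, 2, 3):
            report = run_simulation(cfg.replace(n_positions=n),
                                    tmp_path / f"n{n}")
            assert report.warnings == 0
        report = run_simulation(cfg.replace(n_positions=4), tmp_path / "n4")
        assert report.warnings > 0
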