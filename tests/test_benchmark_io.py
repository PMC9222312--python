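"""Record I/O, benchmark runner, and CLI plumbing."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fwavekit.benchmark import BenchmarkSpec, make_ensemble, run_benchmark
from fwavekit.cli import main as cli_main
from fwavekit.decompose import DualQConfig
from fwavekit.io import EcgRecord, read_record, write_record
from fwavekit.simulate import compose_record, make_fwave_params

FAST_DECOMP = DualQConfig(lambda_osc=2.0, lambda_trn=1.5, n_iter=60, tol=0.0)


class TestIo:
    def test_af_record_roundtrip(self, tmp_path):
        rec = compose_record(
            make_fwave_params("A", "II"), noise_level=10.0, duration_s=3.0, seed=5
        )
        p = tmp_path / "rec.tsv"
        write_record(rec, p)
        back = read_record(p)
        np.testing.assert_allclose(back.x, rec.x, rtol=1e-9)
        np.testing.assert_allclose(back.fwave_truth, rec.fwave_truth, rtol=1e-9)
        assert back.beat_annotations == rec.beat_annotations
        assert back.fs == rec.fs

    def test_plain_record_roundtrip(self, tmp_path, rng):
        rec = EcgRecord(x=rng.standard_normal(100), fs=250.0)
        p = tmp_path / "plain.tsv"
        write_record(rec, p)
        back = read_record(p)
        assert isinstance(back, EcgRecord)
        np.testing.assert_allclose(back.x, rec.x, rtol=1e-9)

    def test_missing_fs_header_named_in_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("# no sampling rate here\nx\n1.0\n2.0\n")
        with pytest.raises(ValueError, match="fs"):
            read_record(p)


class TestBenchmark:
    def test_abs_only_no_fwave_near_zero_rmse(self):
        # identical-beat records without F-wave or noise: ABS cancels everything
        spec = BenchmarkSpec(
            fwave_type="B", n_records=1, seed=0, methods=("abs",),
            decomposition=FAST_DECOMP,
        )
        recs = make_ensemble(spec, 0.0)
        from fwavekit.baselines import abs_extract
        from fwavekit.simulate import AfRecord

        rec = recs[0]
        bare = AfRecord(
            x=rec.ventricular, fwave_truth=np.zeros_like(rec.x),
            ventricular=rec.ventricular, noise=np.zeros_like(rec.x),
            fs=rec.fs, beat_annotations=rec.beat_annotations,
        )
        est = abs_extract(bare)
        assert np.sqrt(np.mean(est**2)) < 0.05 * np.max(np.abs(bare.x))

    def test_deterministic_given_seed(self):
        spec = BenchmarkSpec(
            fwave_type="B", n_records=2, seed=7, methods=("abs", "pca"),
        )
        a = run_benchmark(spec).records
        b = run_benchmark(spec).records
        pd.testing.assert_frame_equal(a, b)

    def test_record_streams_stable_under_n_records(self):
        small = make_ensemble(BenchmarkSpec(n_records=2, seed=3), 0.0)
        large = make_ensemble(BenchmarkSpec(n_records=4, seed=3), 0.0)
        np.testing.assert_array_equal(small[1].x, large[1].x)

    def test_proposed_beats_baselines_under_noise(self):
        """The ordering claim on noisy records: resonance decomposition yields
        lower mean RMSE than both template baselines."""
        spec = BenchmarkSpec(
            fwave_type="B", lead="II", noise_levels_mv=(0.02,), n_records=6,
            seed=17, decomposition=DualQConfig(lambda_osc=2.0, lambda_trn=1.4),
        )
        res = run_benchmark(spec)
        m = res.summary[("rmse", "mean")]
        assert m[(0.02, "proposed")] < m[(0.02, "abs")]
        assert m[(0.02, "proposed")] < m[(0.02, "pca")]

    def test_summary_text_mentions_all_methods(self):
        spec = BenchmarkSpec(
            n_records=1, seed=2, methods=("abs", "pca"), duration_s=10.0
        )
        txt = run_benchmark(spec).summary_text()
        assert "abs" in txt and "pca" in txt


class TestCli:
    def test_simulate_decompose_evaluate_chain(self, tmp_path):
        runner = CliRunner()
        rec_path = tmp_path / "rec.tsv"
        out_path = tmp_path / "comp.tsv"
        r = runner.invoke(
            cli_main,
            ["simulate", "--type", "B", "--duration", "4", "--seed", "1",
             "--out", str(rec_path)],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["decompose", "--input", str(rec_path), "--n-iter", "40",
             "--lambda-osc", "2", "--lambda-trn", "1.5", "--out", str(out_path)],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["evaluate", "--input", str(out_path)])
        assert r.exit_code == 0, r.output
        assert "rmse_uV" in r.output and "dominant_freq_Hz" in r.output

    def test_optimize_q_report(self, tmp_path):
        runner = CliRunner()
        rec_path = tmp_path / "rec.tsv"
        runner.invoke(
            cli_main,
            ["simulate", "--type", "B", "--duration", "1", "--seed", "2",
             "--out", str(rec_path)],
        )
        report = tmp_path / "ga.txt"
        r = runner.invoke(
            cli_main,
            ["optimize-q", "--input", str(rec_path), "--pop-size", "6",
             "--generations", "2", "--seed", "0", "--report", str(report)],
        )
        assert r.exit_code == 0, r.output
        text = report.read_text()
        assert "q_high" in text and "trace" in text

    def test_benchmark_csv(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "bench.csv"
        r = runner.invoke(
            cli_main,
            ["benchmark", "--type", "B", "--n-records", "1", "--seed", "4",
             "--noise-mv", "0", "--out-csv", str(out)],
        )
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out)
        assert set(df["method"]) == {"proposed", "abs", "pca"}
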