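"""Scenario generation: determinism, round trips, calibration, tables, I/O."""

import numpy as np
import pandas as pd
import pytest

from boast31p import (
    FermiPulse,
    InvalidParameterError,
    b1_map_from_phase_pair,
    estimate_all,
    matched_filter_snr,
)
from boast31p.synthetic_data import (
    calf_config,
    cardiac_config,
    generate_b1_phase_pair,
    generate_literature_tables,
    generate_scenario,
    phantom_config,
    saturation_transfer_set_from,
)


def noiseless(ds):
    ds.amplitudes["amplitude"] = ds.amplitudes["true_amplitude"]
    return ds


class TestScenario:
    def test_identical_seed_gives_bitwise_identical_dataset(self):
        a = generate_scenario(cardiac_config(seed=5))
        b = generate_scenario(cardiac_config(seed=5))
        pd.testing.assert_frame_equal(a.amplitudes, b.amplitudes)
        assert np.array_equal(a.phase_pos, b.phase_pos)

    def test_target_voxel_receives_nominal_flips(self):
        cfg = cardiac_config(seed=0)
        ds = generate_scenario(cfg)
        assert ds.flip_alpha[cfg.target_voxel] == pytest.approx(16.0)
        assert ds.flip_beta[cfg.target_voxel] == pytest.approx(64.0)
        assert np.allclose(ds.flip_beta, 4.0 * ds.flip_alpha)

    def test_noiseless_target_voxel_round_trip_is_exact(self):
        cfg = cardiac_config(seed=2)
        ds = noiseless(generate_scenario(cfg))
        res = estimate_all(saturation_transfer_set_from(ds), n_draws=0)
        assert res.kf == pytest.approx(cfg.pools.kf, rel=1e-9)
        assert res.q == pytest.approx(cfg.spillover_q, rel=1e-12)

    def test_calf_scenario_uses_muscle_conditions(self):
        cfg = calf_config(seed=0)
        assert cfg.pools.kf == 0.28
        assert cfg.pools.pcr_atp_ratio == pytest.approx(4.0)
        ds = noiseless(generate_scenario(cfg))
        res = estimate_all(saturation_transfer_set_from(ds), n_draws=0)
        assert res.kf == pytest.approx(0.28, rel=1e-9)

    def test_phantom_has_no_exchange(self):
        ds = noiseless(generate_scenario(phantom_config(seed=0)))
        res = estimate_all(saturation_transfer_set_from(ds), n_draws=0)
        assert res.kf == pytest.approx(0.0, abs=1e-10)

    def test_truth_record_reproduces_amplitude_table(self):
        cfg = cardiac_config(seed=4)
        ds = generate_scenario(cfg)
        v = cfg.target_voxel
        rec = ds.truth["noiseless"][v][6]  # beta control scan
        row = ds.amplitudes[
            (ds.amplitudes.voxel_id == v)
            & (ds.amplitudes.scan_step == 6)
            & (ds.amplitudes.metabolite == "pcr")
        ]
        assert row.true_amplitude.iloc[0] == rec["pcr"]

    def test_noise_calibration_hits_target_snr(self):
        """Matched-filter PCr SNR of the target beta-control FID ~ 13."""
        cfg = cardiac_config(seed=6)
        ds = generate_scenario(cfg, make_fids=True)
        snrs = []
        for seed in range(5):
            d = generate_scenario(cardiac_config(seed=seed), make_fids=True)
            fid = d.fids[(cfg.target_voxel, 6)]
            snrs.append(matched_filter_snr(fid, cfg.linewidth_hz))
        assert np.mean(snrs) == pytest.approx(13.0, rel=0.25)

    def test_unreachable_target_raises(self):
        with pytest.raises((InvalidParameterError, IndexError)):
            generate_scenario(cardiac_config(seed=0, target_voxel=999))


class TestPhasePair:
    def test_noiseless_round_trip_exact(self):
        cfg = cardiac_config(seed=0)
        ds = generate_scenario(cfg)
        b1 = b1_map_from_phase_pair(ds.phase_pos, ds.phase_neg, cfg.bs_pulse)
        assert np.max(np.abs(b1 - ds.b1_map) / ds.b1_map) < 1e-6

    def test_zero_field_gives_zero_phases(self):
        pos, neg = generate_b1_phase_pair(np.zeros(4), FermiPulse(peak_gamma_b1=100.0))
        assert np.all(pos == 0.0) and np.all(neg == 0.0)

    def test_phase_noise_produces_b1_scatter(self, rng):
        field = np.full(2000, 300.0)
        pulse = FermiPulse(peak_gamma_b1=100.0)
        pos, neg = generate_b1_phase_pair(field, pulse, noise_sd=0.002, rng=rng)
        b1 = b1_map_from_phase_pair(pos, neg, pulse)
        cv = np.nanstd(b1) / np.nanmean(b1)
        assert 0.0 < cv < 0.2


class TestLiteratureTables:
    def test_shapes_and_pool_sizes(self):
        t = generate_literature_tables()
        assert len(t["concentrations"]) == 11
        assert len(t["cardiac_study"]) == 10
        normal = t["kf_cohorts"].query("group == 'normal_rest'")
        assert normal.n.sum() == 97


class TestIoRoundTrips:
    def test_amplitude_csv(self, tmp_path):
        from boast31p import io

        ds = generate_scenario(cardiac_config(seed=1))
        path = tmp_path / "amps.csv"
        io.write_amplitudes_csv(ds.amplitudes, path)
        back = io.read_amplitudes_csv(path)
        assert np.allclose(back.amplitude, ds.amplitudes.amplitude)

    def test_fid_binary_with_sidecar(self, tmp_path, rng):
        from boast31p import io
        from boast31p.spectral_fitting import FidData

        fid = FidData(rng.standard_normal(64) + 1j * rng.standard_normal(64), 1 / 6000)
        io.write_fid(fid, tmp_path / "x.bin", voxel=3)
        back = io.read_fid(tmp_path / "x.bin")
        assert back.dwell == fid.dwell
        assert np.allclose(back.samples, fid.samples, atol=1e-6)

    def test_map_csv_with_header(self, tmp_path):
        from boast31p import io

        arr = np.arange(12.0).reshape(3, 4)
        io.write_map_csv(arr, tmp_path / "m.csv", {"fov_mm": [240, 240]})
        back, meta = io.read_map_csv(tmp_path / "m.csv")
        assert np.allclose(back, arr)
        assert meta["fov_mm"] == [240, 240]

    def test_params_json(self):
        from boast31p import io
        from boast31p.exchange_model import PoolSystem

        pools = PoolSystem(kf=0.28)
        back = io.params_from_json(io.params_to_json(pools))
        assert back == pools


class TestCli:
    def test_simulate_and_optimize_smoke(self, tmp_path):
        from click.testing import CliRunner

        from boast31p.cli import main

        runner = CliRunner()
        out = tmp_path / "run"
        res = runner.invoke(main, ["simulate", "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "amplitudes.csv").exists()
        res = runner.invoke(
            main,
            ["optimize-protocol", "--seed", "1", "--out", str(out),
             "--n-draws", "300", "--alpha-max", "20"],
        )
        assert res.exit_code == 0, res.output
        assert (out / "optimum.json").exists()
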