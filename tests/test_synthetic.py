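"""Generator contracts: closed forms, determinism, ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from mifkit import assembly, geometry, relaxation, synthetic
from mifkit.relaxation import T1_DELAYS_MS, T2_DELAYS_MS

from conftest import grid_rate_oracle


def truth_with_rate(r1=1.0, r2=50.0, noe=0.8, n=1, seed=0):
    return synthetic.GroundTruth(
        per_residue_rates={i: (r1, r2, noe) for i in range(1, n + 1)},
        seed=seed)


class TestDecaySeries:
    def test_noiseless_closed_form_on_t1_schedule(self):
        t = truth_with_rate(r1=1.0)
        (s,) = synthetic.gen_decay_series(t, "R1", noise_sd=0.0, h0=100.0)
        expected = 100.0 * np.exp(-0.001 * s.delays_ms)
        np.testing.assert_allclose(s.heights, expected, rtol=0, atol=1e-12)
        assert set(s.delays_ms) == set(T1_DELAYS_MS)

    def test_seed_determinism(self):
        t = truth_with_rate(n=5, seed=7)
        a = synthetic.gen_decay_series(t, "R2", noise_sd=0.02)
        b = synthetic.gen_decay_series(t, "R2", noise_sd=0.02)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.heights, sb.heights)

    def test_noisy_rate_recovered_within_5pct_grid_oracle(self):
        t = truth_with_rate(r2=50.0, seed=11)
        (s,) = synthetic.gen_decay_series(t, "R2", noise_sd=0.02, seed=11)
        r_grid = grid_rate_oracle(s)
        assert abs(r_grid - 50.0) / 50.0 < 0.05

    def test_replicates_share_delay_values(self):
        t = truth_with_rate()
        (s,) = synthetic.gen_decay_series(t, "R2", noise_sd=0.01,
                                          n_replicates=3,
                                          replicate_delays=(1.0, 12.0))
        delays, counts = np.unique(s.delays_ms, return_counts=True)
        assert counts[delays == 1.0] == 3 and counts[delays == 12.0] == 3
        assert counts[delays == 4.0] == 1

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(schedule=[]), "empty"),
        (dict(noise_sd=-0.1), "noise"),
        (dict(schedule=[0.0, 1.0]), "positive"),
    ])
    def test_rejects_bad_inputs(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            synthetic.gen_decay_series(truth_with_rate(), "R1", **kwargs)


class TestShiftPair:
    def test_no_hotspots_no_jitter_is_identity(self):
        t = synthetic.GroundTruth(per_residue_rates={1: (1, 10, 0.8)})
        ref, var = synthetic.gen_shift_pair(t, 50, baseline_jitter_sd=0.0)
        pd.testing.assert_frame_equal(ref, var)

    def test_single_hotspot_offsets_only_that_residue(self):
        t = synthetic.GroundTruth(per_residue_rates={1: (1, 10, 0.8)},
                                  perturbation_hotspots={10: (0.1, 0.5)})
        ref, var = synthetic.gen_shift_pair(t, 50, baseline_jitter_sd=0.0)
        diff_h = (var["dH_ppm"] - ref["dH_ppm"]).abs()
        assert diff_h[10] == pytest.approx(0.1)
        assert (var["dN_ppm"] - ref["dN_ppm"])[10] == pytest.approx(0.5)
        assert diff_h.drop(10).max() == 0.0

    def test_broadened_residues_missing_from_variant(self, default_truth):
        ref, var = synthetic.gen_shift_pair(default_truth, 100)
        assert set(ref.index) - set(var.index) == default_truth.broadened_set

    def test_broadening_wins_over_hotspot(self, caplog):
        t = synthetic.GroundTruth(per_residue_rates={1: (1, 10, 0.8)},
                                  perturbation_hotspots={5: (0.1, 0.5)},
                                  broadened_set={5})
        with caplog.at_level("WARNING"):
            _, var = synthetic.gen_shift_pair(t, 20)
        assert 5 not in var.index
        assert "broadening wins" in caplog.text

    def test_out_of_range_hotspot_rejected(self):
        t = synthetic.GroundTruth(per_residue_rates={1: (1, 10, 0.8)},
                                  perturbation_hotspots={99: (0.1, 0.5)})
        with pytest.raises(ValueError, match="outside"):
            synthetic.gen_shift_pair(t, 50)


class TestTrimerShell:
    def test_uniform_shell_has_constant_analytic_radius(self):
        shell = synthetic.gen_trimer_shell(5.0, 0.0, 1.7)
        axis = geometry.detect_symmetry_axis(shell)
        prof = geometry.channel_profile(shell, axis)
        np.testing.assert_allclose(prof.samples["radius"], 3.3, atol=1e-9)

    def test_constricted_gate_radius(self):
        shell = synthetic.gen_trimer_shell(5.0, 2.0, 1.7)
        axis = geometry.detect_symmetry_axis(shell)
        prof = geometry.channel_profile(shell, axis)
        assert prof.gate_radius == pytest.approx(1.3, abs=1e-9)
        assert abs(prof.gate_z) <= 1.0   # within the slab of the gate ring
        assert prof.samples["radius"].max() == pytest.approx(3.3, abs=1e-9)

    def test_closed_channel_rejected(self):
        with pytest.raises(ValueError, match="closed channel"):
            synthetic.gen_trimer_shell(5.0, 3.5, 1.7)

    def test_thiol_triangle_separation(self):
        shell = synthetic.gen_trimer_shell(8.0, 0.0, 1.7, thiol_distance=6.5)
        d, chains, _ = geometry.min_intersubunit_distance(shell, 4, "SG")
        assert d == pytest.approx(6.5, abs=1e-9)


class TestKineticsAndMelt:
    def test_noiseless_mm_exact_recovery(self):
        table = synthetic.gen_mm_dataset(10.0, 0.5)
        fit = assembly.fit_michaelis_menten(table, 50.0)
        assert fit.kcat == pytest.approx(10.0, rel=1e-6)
        assert fit.km == pytest.approx(0.5, rel=1e-6)

    def test_half_saturation_identity(self):
        km = 0.4
        table = synthetic.gen_mm_dataset(10.0, km, substrate_grid=[km],
                                         n_replicates=1)
        vmax = 10.0 * 50.0 / 1000.0
        assert table["v"].iloc[0] == pytest.approx(vmax / 2)

    def test_noisy_efficiency_within_10pct_of_grid_oracle(self):
        table = synthetic.gen_mm_dataset(10.0, 0.5, noise_sd=0.05, seed=9)
        s = table["S_mM"].to_numpy()
        v = table["v"].to_numpy()
        kcats = np.linspace(5, 15, 101)
        kms = np.linspace(0.1, 1.5, 141)
        e0 = 0.05
        pred = (kcats[:, None, None] * e0 * s[None, None, :]
                / (kms[None, :, None] + s[None, None, :]))
        sse = ((pred - v) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        eff_grid = kcats[i] / kms[j]
        fit = assembly.fit_michaelis_menten(table, 50.0)
        assert abs(fit.efficiency - eff_grid) / eff_grid < 0.10
        assert abs(fit.efficiency - 20.0) / 20.0 < 0.10

    def test_melt_midpoint_identity_at_tm(self):
        tm = 75.0
        curve = synthetic.gen_melt_curve(tm, 400.0,
                                         t_grid=np.array([50.0, tm, 95.0]))
        bf = -20.0 + 0.01 * tm
        bu = -4.0 + 0.01 * tm
        assert curve["signal"].iloc[1] == pytest.approx((bf + bu) / 2)

    def test_noiseless_melt_recovery(self):
        fit = assembly.fit_melt(synthetic.gen_melt_curve(75.0, 400.0))
        assert abs(fit.tm - 75.0) < 0.05

    def test_noisy_tm_within_half_degree_over_20_seeds(self):
        errs = [abs(assembly.fit_melt(
            synthetic.gen_melt_curve(75.0, 400.0, noise_sd=0.02,
                                     seed=seed)).tm - 75.0)
            for seed in range(20)]
        assert np.mean(errs) < 0.5
        assert np.mean(errs) < 0.1   # recovery bias is far below noise level

    def test_nonpositive_dh_rejected(self):
        with pytest.raises(ValueError, match="dH"):
            synthetic.gen_melt_curve(75.0, -10.0)


class TestGroundTruth:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            synthetic.GroundTruth(per_residue_rates={1: (-1.0, 10, 0.5)})
        with pytest.raises(ValueError, match="NOE"):
            synthetic.GroundTruth(per_residue_rates={1: (1.0, 10, 1.5)})

    def test_truth_sidecar_roundtrip(self, tmp_path, small_truth):
        path = tmp_path / "truth.json"
        small_truth.to_json(path)
        import json
        data = json.loads(path.read_text())
        assert data["seed"] == small_truth.seed
        assert sorted(data["broadened_set"]) == sorted(small_truth.broadened_set)
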