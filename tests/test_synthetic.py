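"""Generator ground truth: analytic volumes, programmed COM/COP, cohorts."""

import numpy as np
import pytest

from respmech.chestwall import build_grid, volume_series
from respmech.pipeline import default_grid_spec
from respmech.posture import cop_from_forceplate, default_segment_model, whole_body_com
from respmech.synthetic import (
    SyntheticConfig,
    breathing_waveform,
    generate_body,
    generate_cohort,
    generate_plate_and_emg,
    generate_trial,
    generate_trunk,
)


class TestBreathingWaveform:
    def test_range_and_extrema(self):
        cfg = SyntheticConfig()
        t = np.arange(0, 2 * cfg.breath_period, 0.001)
        w = breathing_waveform(t, cfg)
        assert w.min() >= 0.0 and w.max() <= 1.0
        peak_t = t[np.argmax(w[t < cfg.breath_period])]
        assert peak_t == pytest.approx(cfg.Ti, abs=0.002)

    def test_ti_te_partition_period(self):
        cfg = SyntheticConfig(breathing_rate_bpm=12.0, ti_te_ratio=0.5)
        assert cfg.Ti + cfg.Te == pytest.approx(cfg.breath_period)
        assert cfg.Ti / cfg.Te == pytest.approx(0.5)


class TestTrunk:
    def test_static_config_constant_volume(self):
        cfg = SyntheticConfig(tidal_volume=1e-12, marker_noise_mm=0.0)
        _, analytic = generate_trunk(cfg)
        assert analytic.total.std() < 1e-9

    def test_band_excursions_follow_weights(self):
        """Tidal 0.8 L with weights (.2, .5, .3) puts 0.16/0.40/0.24 L into
        the bands, by construction of the generating radii."""
        cfg = SyntheticConfig(
            tidal_volume=0.8, compartment_weights=(0.2, 0.5, 0.3), marker_noise_mm=0.0
        )
        _, analytic = generate_trunk(cfg)
        for name, target in zip(
            ("upper_thoracic", "lower_thoracic", "abdominal"), (0.16, 0.40, 0.24)
        ):
            band = analytic.compartments[name]
            # the sampled waveform peak sits within half a sample of w = 1
            assert band.max() - band.min() == pytest.approx(target, rel=1e-4)

    def test_mesh_volume_matches_analytic_closed_form(self, default_grid):
        """The volumetry stage reproduces the generator's closed-form band
        volumes; both describe the same prismatoid stack."""
        cfg = SyntheticConfig(marker_noise_mm=0.0)
        markers, analytic = generate_trunk(cfg)
        measured = volume_series(markers, default_grid)
        np.testing.assert_allclose(measured.total, analytic.total, rtol=1e-9)
        for k in analytic.compartments:
            np.testing.assert_allclose(
                measured.compartments[k], analytic.compartments[k], rtol=1e-9
            )


class TestBody:
    def test_zero_oscillation_constant_angles(self):
        cfg = SyntheticConfig(
            joint_amplitudes={"hip": (0, 0, 0), "knee": (0, 0, 0), "ankle": (0, 0, 0)},
            marker_noise_mm=0.0,
        )
        markers, _, rom = generate_body(cfg)
        assert all(v == 0.0 for planes in rom.values() for v in planes.values())
        knee = markers.get("RKNE")
        # joints only translate rigidly with the root: knee-hip vector fixed
        rel = knee - markers.get("RHIP")
        assert np.ptp(rel, axis=0).max() < 1e-9

    def test_programmed_rom_is_config_echo(self):
        cfg = SyntheticConfig()
        _, _, rom = generate_body(cfg)
        assert rom["knee"]["sagittal"] == 2 * cfg.joint_amplitudes["knee"][0]

    def test_com_follows_programmed_mixture(self):
        """kappa = 1: noiseless COM X correlates perfectly with breathing."""
        cfg = SyntheticConfig(kappa=1.0, marker_noise_mm=0.0)
        markers, com_truth, _ = generate_body(cfg)
        t = com_truth.time
        w = breathing_waveform(t, cfg)
        r = np.corrcoef(com_truth.com[:, 0], w)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        # and the segment-model COM of the generated markers IS that target
        com_pipe = whole_body_com(markers, default_segment_model())
        np.testing.assert_allclose(com_pipe.com, com_truth.com, atol=1e-9)


class TestPlateAndEmg:
    def test_static_body_cop_at_com_projection(self):
        cfg = SyntheticConfig(
            sway_amplitude=(0.0, 0.0, 0.0), kappa=0.0,
            marker_noise_mm=0.0, cop_noise_m=0.0,
        )
        _, com_truth, _ = generate_body(cfg)
        plate, _ = generate_plate_and_emg(cfg, com_truth)
        cop = cop_from_forceplate(plate)
        np.testing.assert_allclose(cop.cop_x, com_truth.com[0, 0], atol=1e-12)

    def test_cop_inversion_recovers_generating_cop(self):
        cfg = SyntheticConfig(marker_noise_mm=0.0, cop_noise_m=0.0)
        _, com_truth, _ = generate_body(cfg)
        plate, _ = generate_plate_and_emg(cfg, com_truth)
        cop = cop_from_forceplate(plate)
        t = plate.time
        want_x = np.interp(t, com_truth.time, com_truth.com[:, 0])
        np.testing.assert_allclose(cop.cop_x, want_x, atol=1e-9)

    def test_emg_bursts_have_expected_scale(self):
        cfg = SyntheticConfig()
        _, com_truth, _ = generate_body(cfg)
        _, emg = generate_plate_and_emg(cfg, com_truth)
        assert set(emg.channels) == {
            f"{m}_{s}" for m in ("GMAX", "GMED", "RF", "VM", "VL", "BF", "MG", "TA")
            for s in "RL"
        }
        x = emg.channels["TA_R"]
        assert np.abs(x).max() <= cfg.emg_burst_mv * 1.5


class TestDeterminismAndTruth:
    def test_seeded_generation_is_bit_reproducible(self):
        a = generate_trial(SyntheticConfig(seed=7))
        b = generate_trial(SyntheticConfig(seed=7))
        np.testing.assert_array_equal(
            a.bundle.markers.positions, b.bundle.markers.positions
        )
        np.testing.assert_array_equal(a.bundle.plate.forces, b.bundle.plate.forces)
        np.testing.assert_array_equal(
            a.bundle.emg.channels["TA_R"], b.bundle.emg.channels["TA_R"]
        )

    def test_different_seeds_differ(self):
        a = generate_trial(SyntheticConfig(seed=1))
        b = generate_trial(SyntheticConfig(seed=2))
        assert not np.allclose(a.bundle.markers.positions, b.bundle.markers.positions)

    def test_truth_volume_matches_mesh_within_discretization(
        self, quiet_trial, default_grid
    ):
        measured = volume_series(quiet_trial.bundle.markers, default_grid)
        np.testing.assert_allclose(
            measured.total, quiet_trial.truth.analytic_volume.total, rtol=1e-6
        )


class TestCohort:
    def test_schema_and_groups(self):
        df = generate_cohort(n_per_group=5, seed=0)
        assert list(df.columns) == ["outcome", "family", "group", "participant", "value"]
        assert set(df["group"]) == {"LP", "BP"}
        counts = df.groupby(["outcome", "group"]).size()
        assert (counts == 5).all()

    def test_null_cohort_groups_match_in_expectation(self):
        """With no programmed effect, group means agree to within 2 SEM when
        averaged over seeds."""
        diffs, sems = [], []
        for seed in range(10):
            df = generate_cohort(n_per_group=21, seed=seed)
            sub = df[df["outcome"] == "inspiratory_time_s"]
            lp = sub[sub["group"] == "LP"]["value"]
            bp = sub[sub["group"] == "BP"]["value"]
            diffs.append(lp.mean() - bp.mean())
            sems.append(np.sqrt(lp.var() / 21 + bp.var() / 21))
        assert abs(np.mean(diffs)) < 2 * np.mean(sems) / np.sqrt(10)

    def test_programmed_shift_detected_with_expected_g(self):
        """A 1-pooled-SD shift at n = 21 lands g near 1 (sampling noise of
        g at this n is about 0.33)."""
        from respmech.group_stats import hedges_g_from_samples, GroupSample

        gvals = []
        for seed in range(10):
            df = generate_cohort(
                n_per_group=21, effect_spec={"inspiratory_time_s": 0.30}, seed=seed
            )
            sub = df[df["outcome"] == "inspiratory_time_s"]
            a = GroupSample("ti", "LP", sub[sub["group"] == "LP"]["value"].to_numpy())
            b = GroupSample("ti", "BP", sub[sub["group"] == "BP"]["value"].to_numpy())
            gvals.append(hedges_g_from_samples(a, b)[0])
        assert np.mean(gvals) == pytest.approx(1.0, abs=0.35)

    def test_unknown_effect_outcome_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            generate_cohort(effect_spec={"nonexistent": 1.0})
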