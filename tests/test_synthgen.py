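"""Ground-truth properties of the synthetic EEG, cohort and fixation data."""

import numpy as np
import pandas as pd
import pytest

from fpvstag.paradigm import DEFAULT_CHANNELS, StimulationParadigm
from fpvstag.spectral import compute_spectrum, target_bin
from fpvstag.stats import ModelSpec, fit_model
from fpvstag.synthgen import (
    SimulationConfig,
    default_aois,
    eeg_from_frame,
    eeg_to_frame,
    simulate_cohort,
    simulate_eeg,
    simulate_fixations,
    snap_frequency,
    stream_harmonic_frequencies,
)


class TestSeedDeterminism:
    def test_identical_config_and_seed_is_bit_identical(self, noisy_cfg):
        p = StimulationParadigm()
        a = simulate_eeg(p, noisy_cfg, "s1", "social")
        b = simulate_eeg(p, noisy_cfg, "s1", "social")
        assert np.array_equal(a.samples, b.samples)
        ca = simulate_cohort(noisy_cfg)
        cb = simulate_cohort(noisy_cfg)
        pd.testing.assert_frame_equal(ca.oddball, cb.oddball)
        aois = default_aois(noisy_cfg.screen_px)
        probs = {"left": 0.5, "right": 0.3, "outside": 0.2}
        fa = simulate_fixations(aois, probs, 20, noisy_cfg, "s1", "t")
        fb = simulate_fixations(aois, probs, 20, noisy_cfg, "s1", "t")
        assert fa == fb

    def test_different_subjects_get_different_noise(self, noisy_cfg):
        p = StimulationParadigm()
        a = simulate_eeg(p, noisy_cfg, "s1", "social")
        b = simulate_eeg(p, noisy_cfg, "s2", "social")
        assert not np.array_equal(a.samples, b.samples)


class TestSpectralGroundTruth:
    def test_noise_free_bins_match_configured_amplitudes_exactly(
        self, noise_free_cfg, oddball_paradigm
    ):
        rec = simulate_eeg(oddball_paradigm, noise_free_cfg, "s1", "social")
        spec = compute_spectrum(rec)
        amps = spec.channel("Oz")
        expected = {}
        for k, a in enumerate(noise_free_cfg.base_amplitudes_uv, start=1):
            expected[5.0 * k] = a
        for f, a in zip((1.25, 2.5, 3.75, 6.25, 7.5),
                        noise_free_cfg.oddball_amplitudes_uv):
            expected[f] = a
        tagged_bins = []
        for f, a in expected.items():
            kbin = target_bin(spec, f)
            tagged_bins.append(kbin)
            assert amps[kbin] == pytest.approx(a, abs=1e-9)
        mask = np.ones(spec.n_bins, bool)
        mask[tagged_bins] = False
        assert np.all(amps[mask] <= 1e-9)

    def test_pure_tone_config(self):
        cfg = SimulationConfig(
            seed=1, pink_sd_uv=0, white_sd_uv=0,
            base_amplitudes_uv=(1.0,), oddball_amplitudes_uv=(),
            roi_gains_base={"LOT": 1, "MO": 1, "ROT": 1},
        )
        spec = compute_spectrum(simulate_eeg(StimulationParadigm(), cfg, "s"))
        amps = spec.channel("P10")
        k = target_bin(spec, 5.0)
        assert amps[k] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.delete(amps, k) <= 1e-9)

    def test_roi_topography_gains_scale_channel_amplitudes(self):
        cfg = SimulationConfig(
            seed=1, pink_sd_uv=0, white_sd_uv=0,
            base_amplitudes_uv=(1.0,), oddball_amplitudes_uv=(),
            roi_gains_base={"LOT": 0.5, "MO": 2.0, "ROT": 1.0},
        )
        spec = compute_spectrum(simulate_eeg(StimulationParadigm(), cfg, "s"))
        k = target_bin(spec, 5.0)
        assert spec.channel("P7")[k] == pytest.approx(0.5, abs=1e-9)   # LOT
        assert spec.channel("Oz")[k] == pytest.approx(2.0, abs=1e-9)   # MO
        assert spec.channel("P8")[k] == pytest.approx(1.0, abs=1e-9)   # ROT

    def test_multiinput_streams_snap_to_the_bin_grid(
        self, noise_free_cfg, multiinput_paradigm
    ):
        rec = simulate_eeg(multiinput_paradigm, noise_free_cfg, "s1")
        spec = compute_spectrum(rec)
        assert snap_frequency(4.61, 60.0) == pytest.approx(277 / 60)
        for rate in (4.61, 5.0):
            freqs = stream_harmonic_frequencies(rate, 4, 60.0)
            for f, a in zip(freqs, noise_free_cfg.stream_amplitudes_uv):
                k = target_bin(spec, f)
                assert spec.channel("Iz")[k] == pytest.approx(a, abs=1e-9)

    def test_strict_alignment_rejects_off_grid_rates(self, noise_free_cfg):
        p = StimulationParadigm(kind="multi_input")
        with pytest.raises(ValueError, match="4.61"):
            simulate_eeg(p, noise_free_cfg, "s1", align="strict")


class TestCohort:
    def test_zero_variability_yields_configured_means_exactly(self):
        cfg = SimulationConfig(
            seed=2, n_control=2, n_adversity=2,
            sigma_within=0.0, sigma_subject=0.0, sigma_latent=0.0,
            gaze_sigma_within=0.0, gaze_sigma_subject=0.0,
            threat_content_slope_sd=0.0, neglect_content_slope_sd=0.0,
        )
        coh = simulate_cohort(cfg)
        odd = coh.oddball
        roi_off = {"LOT": -0.1, "MO": 0.05, "ROT": 0.05}
        for row in odd.itertuples():
            mu = cfg.oddball_grand_mean_uv + roi_off[row.roi]
            if row.group == "control":
                xc = 0.5 if row.content == "social" else -0.5
                mu += cfg.group_content_gap_sd * cfg.sigma_within * xc
            assert row.y == pytest.approx(mu, abs=1e-12)
        neu = coh.multiinput_gaze
        for row in neu.itertuples():
            xv = 0.5 if row.valence == "neutral" else -0.5
            # controls have adversity z-score zero by construction
            expect = cfg.gaze_base_proportion + xv * cfg.gaze_valence_main
            if row.group == "control":
                assert row.y == pytest.approx(expect, abs=1e-12)

    def test_group_sizes_and_gaze_subset(self):
        cfg = SimulationConfig(seed=3, n_control=10, n_adversity=12,
                               n_control_gaze=6, n_adversity_gaze=8)
        coh = simulate_cohort(cfg)
        counts = coh.covariates["group"].value_counts()
        assert counts["control"] == 10 and counts["adversity"] == 12
        gaze_groups = (
            coh.multiinput_gaze.drop_duplicates("subject")["group"].value_counts()
        )
        assert gaze_groups["control"] == 6 and gaze_groups["adversity"] == 8
        assert len(coh.oddball) == 22 * 2 * 3
        assert len(coh.multiinput_neural) == 22 * 2 * 2 * 2

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_control=1)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(base_amplitudes_uv=(-1.0,))

    def test_adversity_scores_concentrate_in_the_adversity_group(self):
        coh = simulate_cohort(SimulationConfig(seed=4))
        means = coh.covariates.groupby("group")["adversity"].mean()
        assert means["adversity"] > means["control"]

    def test_null_signal_gives_null_downstream_response(self):
        """Oddball amplitudes of zero leave only noise at the oddball bins."""
        from fpvstag.harmonics import ROIS, oddball_harmonics, summed_response

        cfg = SimulationConfig(
            seed=5, oddball_amplitudes_uv=(0.0,) * 5,
            roi_gains_base={"LOT": 1, "MO": 1, "ROT": 1},
            roi_gains_response={"LOT": 1, "MO": 1, "ROT": 1},
        )
        vals = []
        for s in range(8):
            spec = compute_spectrum(
                simulate_eeg(StimulationParadigm(), cfg, f"s{s}")
            )
            vals.append(
                summed_response(spec, oddball_harmonics(), ROIS[1])
                .summed_baseline_subtracted_uv
            )
        assert abs(np.mean(vals)) < 0.05


class TestEffectRecovery:
    def test_large_n_signs_recovered_by_the_model_suite(self):
        """Each configured effect is recovered in sign on one large-n draw."""
        cfg = SimulationConfig(seed=17, n_control=150, n_adversity=150,
                               n_control_gaze=150, n_adversity_gaze=150)
        coh = simulate_cohort(cfg)
        m1 = fit_model(ModelSpec(1, "oddball"), coh.oddball)
        assert m1.fit.params["group_c:content_c"] > 0
        m3 = fit_model(ModelSpec(3, "oddball"), coh.oddball)
        assert m3.fit.params["threat_z:content_c"] < 0
        mi = fit_model(ModelSpec(1, "multiinput_neural"), coh.multiinput_neural)
        assert mi.fit.params["valence_c"] > 0
        assert mi.fit.params["valence_c:content_c"] > 0
        mg = fit_model(ModelSpec(2, "multiinput_gaze"), coh.multiinput_gaze)
        assert mg.fit.params["adversity_z:valence_c"] < 0


class TestCsvRoundTrip:
    def test_eeg_long_format_round_trips(self, noise_free_cfg):
        p = StimulationParadigm()
        rec = simulate_eeg(p, noise_free_cfg, "s1", "social")
        df = eeg_to_frame(rec)
        back = eeg_from_frame(df, noise_free_cfg.sampling_rate_hz, p)
        assert back.channel_labels == tuple(DEFAULT_CHANNELS)
        assert np.allclose(back.samples, rec.samples)
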