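"""Amplitude normalisation and per-bin statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpvstag.paradigm import DEFAULT_CHANNELS, EEGRecording, StimulationParadigm
from fpvstag.spectral import (
    AmplitudeSpectrum,
    bin_stats,
    bin_stats_from_values,
    average_epochs,
    compute_spectrum,
    neighborhood,
    target_bin,
)


def _recording(signal: np.ndarray, fs: float = 256.0) -> EEGRecording:
    data = np.tile(signal, (len(DEFAULT_CHANNELS), 1))
    return EEGRecording(
        channel_labels=DEFAULT_CHANNELS,
        sampling_rate_hz=fs,
        samples=data,
        paradigm=StimulationParadigm(),
        subject_id="s",
    )


class TestComputeSpectrum:
    def test_pure_tone_reads_its_amplitude_in_uv(self):
        fs, dur = 256.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        spec = compute_spectrum(_recording(2.0 * np.sin(2 * np.pi * 5.0 * t), fs))
        amps = spec.channel("Oz")
        k = target_bin(spec, 5.0)
        assert amps[k] == pytest.approx(2.0, abs=1e-9)
        others = np.delete(amps, k)
        assert np.all(others <= 1e-9)

    def test_constant_signal_has_power_only_at_dc(self):
        spec = compute_spectrum(_recording(np.full(2560, 3.0)))
        assert np.all(spec.channel("Oz") <= 1e-9)  # mean removed

    def test_two_tones_superpose_linearly(self):
        fs, dur = 256.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        sig = 0.5 * np.sin(2 * np.pi * 1.25 * t) + 2.0 * np.cos(2 * np.pi * 5.0 * t)
        spec = compute_spectrum(_recording(sig, fs))
        amps = spec.channel("P7")
        assert amps[target_bin(spec, 1.25)] == pytest.approx(0.5, abs=1e-9)
        assert amps[target_bin(spec, 5.0)] == pytest.approx(2.0, abs=1e-9)
        mask = np.ones(spec.n_bins, bool)
        mask[[target_bin(spec, 1.25), target_bin(spec, 5.0)]] = False
        assert np.all(amps[mask] <= 1e-9)

    def test_window_sets_frequency_resolution(self):
        rec = _recording(np.zeros(2560), fs=256.0)
        spec = compute_spectrum(rec, window=(0.0, 5.0))
        assert spec.freq_resolution_hz == pytest.approx(0.2)
        with pytest.raises(ValueError):
            compute_spectrum(rec, window=(2.0, 2.0))

    def test_epoch_averaging_keeps_phase_locked_signal(self):
        fs, dur = 128.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        sig = np.sin(2 * np.pi * 2.0 * t)
        rng = np.random.default_rng(5)
        epochs = [_recording(sig + rng.normal(0, 1, t.size), fs) for _ in range(64)]
        spec = compute_spectrum(average_epochs(epochs))
        assert spec.channel("Oz")[target_bin(spec, 2.0)] == pytest.approx(1.0, abs=0.1)


class TestTargetBin:
    @pytest.mark.parametrize(
        "resolution,freq,expected",
        [(0.25, 5.0, 20), (1 / 60, 1.25, 75), (1 / 60, 7.5, 450)],
    )
    def test_aligned_frequencies_map_to_bins(self, resolution, freq, expected):
        spec = AmplitudeSpectrum(resolution, np.zeros((1, 600)), ("Oz",))
        assert target_bin(spec, freq) == expected

    def test_misaligned_frequency_is_an_error_naming_the_frequency(self):
        spec = AmplitudeSpectrum(0.25, np.zeros((1, 600)), ("Oz",))
        with pytest.raises(ValueError, match="5.1"):
            target_bin(spec, 5.1)


class TestNeighborhood:
    def test_default_excludes_one_adjacent_bin_per_side(self):
        spec = AmplitudeSpectrum(0.1, np.zeros((1, 300)), ("Oz",))
        nb = neighborhood(spec, 100, n_per_side=10, exclude_adjacent=1)
        assert set(nb.neighbor_bins) == set(range(89, 99)) | set(range(102, 112))
        assert len(nb.neighbor_bins) == 20

    def test_no_exclusion_takes_immediately_adjacent_bins(self):
        spec = AmplitudeSpectrum(0.1, np.zeros((1, 300)), ("Oz",))
        nb = neighborhood(spec, 100, n_per_side=10, exclude_adjacent=0)
        assert set(nb.neighbor_bins) == set(range(90, 100)) | set(range(101, 111))

    def test_edge_target_is_an_error(self):
        spec = AmplitudeSpectrum(0.1, np.zeros((1, 300)), ("Oz",))
        with pytest.raises(ValueError):
            neighborhood(spec, 5, n_per_side=10)


class TestBinStats:
    def test_flat_neighborhood_gives_snr_and_difference_directly(self):
        st_ = bin_stats_from_values(5.0, 2.0, np.full(20, 1.0))
        assert st_.snr == pytest.approx(2.0)
        assert st_.baseline_subtracted_uv == pytest.approx(1.0)
        assert np.isinf(st_.z)  # zero-SD sentinel

    def test_z_is_mean_sd_standardisation(self):
        rng = np.random.default_rng(0)
        neigh = rng.normal(1.0, 0.5, 20)
        st_ = bin_stats_from_values(5.0, 2.0, neigh)
        expected = (2.0 - neigh.mean()) / neigh.std(ddof=1)
        assert st_.z == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_on_toy_spectrum(self):
        # independent recomputation of all three definitions on 32 bins
        rng = np.random.default_rng(7)
        amps = rng.uniform(0.5, 1.5, 32)
        spec = AmplitudeSpectrum(0.5, amps[None, :], ("Oz",))
        st_ = bin_stats(spec, "Oz", frequency_hz=8.0)  # bin 16
        neigh = np.r_[amps[5:15], amps[18:28]]
        assert st_.snr == pytest.approx(amps[16] / neigh.mean(), rel=1e-12)
        assert st_.baseline_subtracted_uv == pytest.approx(
            amps[16] - neigh.mean(), rel=1e-12
        )
        assert st_.z == pytest.approx(
            (amps[16] - neigh.mean()) / neigh.std(ddof=1), rel=1e-12
        )

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 100.0),
        seed=st.integers(0, 10_000),
    )
    def test_scale_equivariance(self, scale, seed):
        """c*x scales amplitude and difference by c; SNR and Z are unchanged."""
        rng = np.random.default_rng(seed)
        amps = rng.uniform(0.2, 2.0, 64)
        s1 = AmplitudeSpectrum(0.5, amps[None, :], ("Oz",))
        s2 = AmplitudeSpectrum(0.5, (scale * amps)[None, :], ("Oz",))
        a = bin_stats(s1, "Oz", 16.0)
        b = bin_stats(s2, "Oz", 16.0)
        assert b.baseline_subtracted_uv == pytest.approx(
            scale * a.baseline_subtracted_uv, rel=1e-9
        )
        assert b.snr == pytest.approx(a.snr, rel=1e-9)
        assert b.z == pytest.approx(a.z, rel=1e-9)

    def test_white_noise_snr_centres_on_one(self):
        """Monte-Carlo null: mean SNR ~ 1, mean difference ~ 0 over many bins."""
        rng = np.random.default_rng(3)
        amps = np.abs(rng.normal(0, 1.0, 3000) + 1j * rng.normal(0, 1.0, 3000))
        spec = AmplitudeSpectrum(0.1, amps[None, :], ("Oz",))
        stats = [bin_stats(spec, "Oz", k * 0.1) for k in range(100, 2900, 2)]
        snrs = np.array([s.snr for s in stats])
        diffs = np.array([s.baseline_subtracted_uv for s in stats])
        assert abs(snrs.mean() - 1.0) < 0.05
        assert abs(diffs.mean()) < 0.05
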