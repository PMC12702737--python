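"""Band-power pipeline: filter response, epoching, PSD, band integration."""

import numpy as np
import pytest

from neuroaffect import (
    EEGRecording,
    InputError,
    band_power,
    bandpass_filter,
    baseline_correct,
    change_scores,
    compute_psd,
    epoch,
    time_domain_descriptors,
)
from neuroaffect.eeg import BANDS, PSDSpectrum, band_power_summary

FS = 128.0


def sinusoid_recording(freq, duration=8.0, amplitude=1.0, n_channels=1,
                       labels=None):
    t = np.arange(int(duration * FS)) / FS
    wave = amplitude * np.sin(2 * np.pi * freq * t)
    samples = np.tile(wave, (n_channels, 1))
    labels = labels or [f"C{i}" for i in range(n_channels)]
    return EEGRecording(channel_labels=labels, fs=FS, samples=samples)


class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        rec = EEGRecording(["a"], FS, np.zeros((1, 512)))
        assert np.allclose(bandpass_filter(rec).samples, 0.0)

    def test_passband_tone_preserved(self):
        rec = sinusoid_recording(6.0)
        out = bandpass_filter(rec)
        # compare RMS on the interior to avoid edge transients
        sl = slice(128, -128)
        ratio = (np.std(out.samples[0, sl]) / np.std(rec.samples[0, sl]))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_subsonic_tone_suppressed(self):
        rec = sinusoid_recording(0.2, duration=20.0)
        out = bandpass_filter(rec)
        assert np.max(np.abs(out.samples[0, 256:-256])) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        rec = sinusoid_recording(6.0)
        with pytest.raises(InputError, match="Nyquist"):
            bandpass_filter(rec, low=1.0, high=70.0)


class TestEpoch:
    @pytest.mark.parametrize("duration, n_expected", [(10.0, 5), (11.0, 5), (4.0, 2)])
    def test_floor_rule(self, duration, n_expected):
        rec = sinusoid_recording(6.0, duration=duration)
        eps = epoch(rec, 2.0)
        assert len(eps) == n_expected
        assert all(e.shape == (1, 256) for e in eps)

    def test_too_short_recording(self):
        rec = sinusoid_recording(6.0, duration=1.0)
        with pytest.raises(InputError, match="shorter"):
            epoch(rec, 2.0)


class TestBaselineCorrect:
    def test_constant_channel_zeroed(self):
        out = baseline_correct(np.full((2, 100), 5.0))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_zero_mean_signal_unchanged(self, rng):
        x = np.sin(2 * np.pi * 6 * np.arange(256) / FS)[None, :]
        assert np.allclose(baseline_correct(x), x, atol=1e-10)

    def test_output_mean_is_zero(self, rng):
        x = rng.normal(3.0, 2.0, size=(4, 256))
        assert np.allclose(baseline_correct(x).mean(axis=-1), 0.0, atol=1e-10)


class TestComputePSD:
    def test_tone_peaks_at_its_bin(self):
        rec = sinusoid_recording(6.0, duration=2.0)
        psd = compute_psd(rec.samples, FS)
        peak = psd.frequencies[np.argmax(psd.power[0])]
        assert peak == pytest.approx(6.0, abs=0.5)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(0.0, 2.0, size=(1, 4096))
        psd = compute_psd(x, FS)
        integral = np.trapezoid(psd.power[0], psd.frequencies)
        assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_zero_signal(self):
        psd = compute_psd(np.zeros((1, 256)), FS)
        assert np.allclose(psd.power, 0.0)


class TestBandPower:
    def test_tone_power_concentrates_in_theta(self):
        rec = sinusoid_recording(6.0, duration=8.0)
        psd = compute_psd(rec.samples, FS)
        theta = band_power(psd, BANDS["theta"])[0]
        total = band_power(psd, (1.0, 50.0))[0]
        assert theta > 0.9 * total

    def test_additivity(self, rng):
        psd = compute_psd(rng.normal(size=(3, 1024)), FS)
        split = band_power(psd, (4.0, 6.0)) + band_power(psd, (6.0, 8.0))
        whole = band_power(psd, (4.0, 8.0))
        assert np.allclose(split, whole, atol=1e-9)

    def test_flat_psd_rectangle(self):
        freqs = np.arange(0.0, 64.0, 0.5)
        psd = PSDSpectrum(freqs, np.full((1, freqs.size), 2.0))
        assert band_power(psd, (4.0, 8.0))[0] == pytest.approx(8.0)

    def test_empty_band_rejected(self, rng):
        psd = compute_psd(rng.normal(size=(1, 256)), FS)
        with pytest.raises(InputError, match="empty band"):
            band_power(psd, (8.0, 8.0))

    def test_nonnegative_for_random_signals(self, rng):
        for _ in range(10):
            psd = compute_psd(rng.normal(size=(2, 512)), FS)
            for band in BANDS.values():
                assert np.all(band_power(psd, band) >= 0)


class TestTimeDomainDescriptors:
    def test_constant_signal_flags_undefined(self):
        mean, sd, skew, kurt = time_domain_descriptors(np.full((1, 100), 7.0))
        assert mean[0] == 7.0 and sd[0] == 0.0
        assert np.isnan(skew[0]) and np.isnan(kurt[0])

    def test_sinusoid_symmetry(self):
        x = np.sin(2 * np.pi * 6 * np.arange(1024) / FS)[None, :]
        _, _, skew, _ = time_domain_descriptors(x)
        assert abs(skew[0]) < 0.05

    def test_gaussian_excess_kurtosis(self, rng):
        x = rng.normal(size=(1, 10_000))
        _, _, _, kurt = time_domain_descriptors(x)
        assert abs(kurt[0]) < 0.2


class TestChangeScores:
    def test_identical_recordings_zero_change(self, rng):
        from neuroaffect import generate_eeg_pair
        pre, _ = generate_eeg_pair(duration=6.0, seed=11)
        scores = change_scores(pre, pre)
        assert scores.theta_change == 0.0 and scores.gamma_change == 0.0

    def test_antisymmetry(self):
        from neuroaffect import generate_eeg_pair
        pre, post = generate_eeg_pair(duration=6.0, theta_multiplier=1.4,
                                      gamma_multiplier=0.7, seed=5)
        fwd = change_scores(pre, post)
        rev = change_scores(post, pre)
        assert fwd.theta_change == pytest.approx(-rev.theta_change, rel=1e-9)
        assert fwd.gamma_change == pytest.approx(-rev.gamma_change, rel=1e-9)

    def test_channel_permutation_equivariance(self, rng):
        from neuroaffect import generate_eeg_pair
        pre, post = generate_eeg_pair(duration=6.0, theta_multiplier=1.3, seed=7)
        perm = rng.permutation(len(pre.channel_labels))
        shuffle = lambda rec: EEGRecording(
            [rec.channel_labels[i] for i in perm], rec.fs,
            rec.samples[perm], rec.condition)
        orig = change_scores(pre, post)
        permuted = change_scores(shuffle(pre), shuffle(post))
        assert permuted.theta_change == pytest.approx(orig.theta_change, rel=1e-12)
        assert permuted.gamma_change == pytest.approx(orig.gamma_change, rel=1e-12)

    def test_missing_channel_set_names_labels(self):
        rec = sinusoid_recording(6.0, n_channels=2, labels=["Fz", "Cz"])
        with pytest.raises(InputError, match="FCz"):
            band_power_summary(rec)
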