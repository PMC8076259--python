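import numpy as np
import pytest

from rodentsleep import io_prep, spectral
from rodentsleep.types import EpochedSignal, Hypnogram, VigilanceState


def _epochs(x, fs=125.0):
    return io_prep.epoch_signal(np.asarray(x, float), fs=fs, epoch_len=4.0)


def _sine_epochs(freq, n_epochs=4, fs=125.0, amp=1.0):
    t = np.arange(int(n_epochs * 4 * fs)) / fs
    return _epochs(amp * np.sin(2 * np.pi * freq * t), fs)


class TestHighpass:
    def test_dc_offset_removed(self, rng):
        x = rng.standard_normal(2000)
        base = spectral.highpass_epochs(_epochs(x))
        shifted = spectral.highpass_epochs(_epochs(x + 5.0))
        assert abs(shifted.epochs.mean() - base.epochs.mean()) < 0.01 * 5.0

    def test_10hz_tone_preserved(self):
        out = spectral.highpass_epochs(_sine_epochs(10.0))
        # interior of each epoch, RMS-based amplitude (edges carry filter transients)
        amplitude = np.sqrt(2) * np.sqrt(np.mean(out.epochs[:, 100:-100] ** 2))
        assert amplitude == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        out = spectral.highpass_epochs(_epochs(np.zeros(2000)))
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spectral.highpass_epochs(_epochs(np.zeros(2000)), cutoff=70.0)


class TestEpochPSD:
    def test_grid_is_quarter_hz(self):
        spec = spectral.epoch_psd(_sine_epochs(10.0))
        assert spec.df == pytest.approx(0.25)
        assert spec.frequencies[0] == 0.0 and spec.frequencies[-1] == 62.5
        assert spec.frequencies.size == 251

    def test_tone_peaks_at_its_frequency(self):
        spec = spectral.epoch_psd(_sine_epochs(10.0))
        assert spec.frequencies[np.argmax(spec.power[0])] == 10.0

    def test_two_tones_dominate(self):
        t = np.arange(500) / 125.0
        x = np.sin(2 * np.pi * 3 * t) + np.sin(2 * np.pi * 8 * t)
        spec = spectral.epoch_psd(_epochs(np.tile(x, 3)))
        top2 = spec.frequencies[np.argsort(spec.power[0])[-2:]]
        assert set(top2) == {3.0, 8.0}

    def test_parseval_consistency(self, rng):
        x = rng.standard_normal((20, 500))
        spec = spectral.epoch_psd(EpochedSignal(x, 4.0, 125.0))
        w = np.hamming(500)
        expected = np.mean((x * w) ** 2, axis=1) * 500 / np.sum(w**2)
        np.testing.assert_allclose(spec.power.sum(axis=1) * 0.25, expected, rtol=0.01)

    def test_wrong_grid_rejected(self):
        with pytest.raises(ValueError, match="0.25 Hz"):
            spectral.epoch_psd(EpochedSignal(np.zeros((2, 250)), 2.0, 125.0))


class TestNormalize:
    def test_sums_to_one(self, rng):
        spec = spectral.epoch_psd(EpochedSignal(rng.standard_normal((50, 500)), 4.0, 125.0))
        norm = spectral.normalize_psd(spec)
        np.testing.assert_allclose(norm.power.sum(axis=1), 1.0, atol=1e-9)

    def test_flat_spectrum_uniform(self):
        spec = spectral.EpochSpectra(np.arange(0, 62.75, 0.25), np.ones((1, 251)))
        norm = spectral.normalize_psd(spec)
        np.testing.assert_allclose(norm.power, 1.0 / 251)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((10, 500))
        a = spectral.normalize_psd(spectral.epoch_psd(EpochedSignal(x, 4.0, 125.0)))
        b = spectral.normalize_psd(spectral.epoch_psd(EpochedSignal(7.3 * x, 4.0, 125.0)))
        np.testing.assert_allclose(a.power, b.power, rtol=1e-9)

    def test_zero_epoch_flagged(self):
        power = np.vstack([np.ones(251), np.zeros(251)])
        norm = spectral.normalize_psd(
            spectral.EpochSpectra(np.arange(0, 62.75, 0.25), power)
        )
        assert norm.valid.tolist() == [True, False]


class TestStateSummary:
    def _spectra(self, power):
        return spectral.EpochSpectra(
            np.arange(0, 62.75, 0.25), power, normalized=True,
            valid=np.ones(power.shape[0], bool),
        )

    def test_identical_epochs_zero_iqr(self):
        row = np.random.default_rng(0).dirichlet(np.ones(251))
        spectra = self._spectra(np.tile(row, (8, 1)))
        hyp = Hypnogram(np.ones(8, dtype=np.int8))
        summ = spectral.state_psd_summary(spectra, hyp, VigilanceState.NREMS, "light")
        sel = (spectra.frequencies >= 1.0) & (spectra.frequencies <= 22.75)
        np.testing.assert_allclose(summ.median, row[sel])
        np.testing.assert_allclose(summ.q75 - summ.q25, 0.0, atol=1e-12)

    def test_permutation_invariance(self, rng):
        power = rng.dirichlet(np.ones(251), size=20)
        states = np.ones(20, dtype=np.int8)
        perm = rng.permutation(20)
        s1 = spectral.state_psd_summary(
            self._spectra(power), Hypnogram(states), VigilanceState.NREMS, "light")
        s2 = spectral.state_psd_summary(
            self._spectra(power[perm]), Hypnogram(states[perm]), VigilanceState.NREMS, "light")
        np.testing.assert_allclose(s1.median, s2.median)

    def test_absent_state_flagged_empty(self):
        spectra = self._spectra(np.ones((5, 251)) / 251)
        summ = spectral.state_psd_summary(
            spectra, Hypnogram(np.zeros(5, dtype=np.int8)), VigilanceState.REMS, "light")
        assert summ.empty

    def test_synth_rems_theta_peak(self, short_synth_recording):
        rec, truth = short_synth_recording
        rec = io_prep.downsample(io_prep.hardware_bandpass(rec), 125.0)
        eeg = io_prep.epoch_signal(rec, channel="eeg")
        spectra = spectral.normalize_psd(
            spectral.epoch_psd(spectral.highpass_epochs(eeg)))
        summ = spectral.state_psd_summary(
            spectra, truth.hypnogram, VigilanceState.REMS, "light")
        peak = summ.frequencies[np.argmax(summ.median)]
        assert 6.0 <= peak <= 9.0


class TestBandPower:
    def test_flat_spectrum_band_fraction(self):
        freqs = np.arange(0, 62.75, 0.25)
        flat = np.ones(251) / 251
        assert spectral.band_power(freqs, flat, "delta") == pytest.approx(17 / 251)

    def test_concentrated_spectrum(self):
        freqs = np.arange(0, 62.75, 0.25)
        power = np.zeros(251)
        power[freqs == 8.0] = 1.0
        assert spectral.band_power(freqs, power, "theta") == 1.0
        for band in ("delta", "alpha", "eta"):
            assert spectral.band_power(freqs, power, band) == 0.0

    def test_bands_subadditive(self, rng):
        freqs = np.arange(0, 62.75, 0.25)
        power = rng.dirichlet(np.ones(251))
        total = sum(spectral.band_power(freqs, power, b) for b in spectral.BANDS)
        assert total <= 1.0 + 1e-12

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            spectral.band_power(np.arange(0, 20.25, 0.25), np.ones(81), (10.0, 30.0))


class TestEtaQC:
    def test_identical_cohort_all_pass(self):
        flags = spectral.eta_qc({f"m{i}": 0.04 for i in range(6)})
        assert all(flags.values())

    def test_attenuated_animal_flagged(self):
        vals = {f"m{i}": 0.04 for i in range(6)}
        vals["m5"] = 0.004
        flags = spectral.eta_qc(vals)
        assert not flags["m5"] and sum(flags.values()) == 5

    def test_tiny_cohort_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            flags = spectral.eta_qc({"a": 0.04, "b": 0.001})
        assert all(flags.values())
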