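"""BSS-CCA decomposition, PSD classification and EMG removal."""

import numpy as np
import pytest
from scipy import signal as sps

from speecherp.containers import Recording
from speecherp.emgcca import (cca_decompose, classify_components, remove_emg,
                              remove_emg_epochs)

FS = 512.0


def _band_power(x, lo, hi, fs=FS):
    f, p = sps.welch(x, fs=fs, nperseg=min(int(fs), len(x)))
    return p[(f >= lo) & (f <= hi)].mean()


class TestDecompose:
    def test_separates_ar1_from_white_noise(self):
        rng = np.random.default_rng(0)
        n = 4096
        ar1 = np.zeros(n)
        for i in range(1, n):
            ar1[i] = 0.99 * ar1[i - 1] + rng.standard_normal()
        white = rng.standard_normal(n)
        X = np.vstack([ar1, white])
        dec = cca_decompose(X)
        assert dec.autocorr[0] > dec.autocorr[1]
        # components match sources up to sign/scale
        c_ar = max(abs(np.corrcoef(dec.components[0], ar1)[0, 1]),
                   abs(np.corrcoef(dec.components[1], ar1)[0, 1]))
        c_wh = max(abs(np.corrcoef(dec.components[0], white)[0, 1]),
                   abs(np.corrcoef(dec.components[1], white)[0, 1]))
        assert c_ar >= 0.95 and c_wh >= 0.95

    def test_full_reconstruction_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 400))
        dec = cca_decompose(X)
        rel = np.abs(dec.reconstruct() - X).max() / np.abs(X).max()
        assert rel < 1e-8

    def test_autocorrelations_non_increasing_and_unit_variance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 1000))
        dec = cca_decompose(X)
        assert np.all(np.diff(dec.autocorr) <= 1e-12)
        assert np.allclose(dec.components.std(axis=1), 1.0)

    def test_all_zero_window_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            cca_decompose(np.zeros((4, 100)))

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="more samples"):
            cca_decompose(np.ones((10, 10)))

    def test_white_noise_canonical_correlations_small(self):
        """Null distribution: at 768 samples the 99th percentile of the
        largest canonical correlation stays below 0.2."""
        tops = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((4, 768))
            tops.append(cca_decompose(X).autocorr[0])
        assert np.quantile(tops, 0.99) < 0.2


class TestClassify:
    def _component_dec(self, comp):
        # minimal decomposition carrying a single component time course
        from speecherp.emgcca import CcaDecomposition
        comp = np.atleast_2d(comp)
        return CcaDecomposition(
            unmixing=np.eye(comp.shape[0]), mixing=np.eye(comp.shape[0]),
            components=comp, autocorr=np.ones(comp.shape[0]),
            mean=np.zeros((comp.shape[0], 1)))

    def test_alpha_band_sinusoid_is_eeg(self):
        t = np.arange(4096) / FS
        cls = classify_components(self._component_dec(np.sin(2 * np.pi * 10 * t)),
                                  FS)
        assert cls[0].label == "EEG"

    def test_emg_band_noise_is_emg(self):
        rng = np.random.default_rng(3)
        sos = sps.butter(4, (15, 30), btype="bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(4096))
        cls = classify_components(self._component_dec(x), FS)
        assert cls[0].label == "EMG"

    def test_zero_eeg_power_flagged_with_infinite_ratio(self):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 60 * t)  # no power below 30 Hz either
        cls = classify_components(self._component_dec(x), FS)
        assert cls[0].label == "EMG"
        assert cls[0].ratio > 1.0

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            classify_components(self._component_dec(np.ones(100)), 50.0)

    def test_threshold_is_inclusive_at_one_fifth(self):
        """Sweeping the band-power ratio in 0.01 steps, the smallest ratio
        flagged EMG equals 0.20."""
        t = np.arange(FS * 8) / FS
        eeg_tone = np.sin(2 * np.pi * 10 * t)
        emg_tone = np.sin(2 * np.pi * 22 * t)
        # calibrate the mixing scale through the estimator itself so the
        # component's *measured* band-power ratio equals the nominal value
        # (band-average powers are linear in the mixing power)
        base = classify_components(self._component_dec(eeg_tone + emg_tone),
                                   FS)[0].ratio
        flagged = []
        for r in np.round(np.arange(0.0, 0.41, 0.01), 2):
            comp = eeg_tone + np.sqrt(r / base) * emg_tone
            cls = classify_components(self._component_dec(comp), FS)
            assert cls[0].ratio == pytest.approx(r, abs=1e-3)
            if cls[0].label == "EMG":
                flagged.append(r)
        assert min(flagged) == 0.20


class TestRemove:
    def test_identity_when_nothing_flagged(self, sim_full, montage):
        rec, _, _ = sim_full
        short = Recording(rec.data[:, :int(FS * 6)], FS, rec.ch_names,
                          rec.ch_types, montage)
        out, report = remove_emg(short, ratio_threshold=np.inf)
        assert np.abs(out.data - short.data).max() < 1e-8 * np.abs(
            short.data).max()
        assert (report["n_components_removed"] == 0).all()

    def test_window_count_on_15s_recording(self):
        rng = np.random.default_rng(4)
        rec = Recording(rng.standard_normal((4, int(FS * 15))), FS,
                        list("ABCD"), ["eeg"] * 4)
        _, report = remove_emg(rec, window_s=1.5)
        assert len(report) == 10

    def test_trailing_partial_window_processed(self):
        rng = np.random.default_rng(5)
        rec = Recording(rng.standard_normal((4, int(FS * 4))), FS,
                        list("ABCD"), ["eeg"] * 4)
        _, report = remove_emg(rec, window_s=1.5)
        # 2 full windows + one 1.0 s partial
        assert len(report) == 3

    def test_recording_shorter_than_window_raises(self):
        rec = Recording(np.ones((2, 100)), FS, ["A", "B"], ["eeg"] * 2)
        with pytest.raises(ValueError, match="shorter"):
            remove_emg(rec, window_s=1.5)

    def test_emg_burst_power_reduced_and_evoked_preserved(
            self, sim_full, sim_clean, montage):
        """Contaminated channels lose >= 80% of 15-30 Hz power while the
        sub-15 Hz response-locked average stays >= 0.95 correlated with the
        artifact-free ground truth."""
        from speecherp.preprocess import (average, epoch, highpass,
                                          ocular_correct, select_trials)
        rec, events, gt = sim_full
        filt = highpass(rec)
        corrected, _ = ocular_correct(filt, events=events)
        cleaned, _ = remove_emg(corrected)
        for ch in ("FT8", "FT7", "T7"):
            i = rec.ch_names.index(ch)
            before = _band_power(corrected.data[i], 15, 30)
            after = _band_power(cleaned.data[i], 15, 30)
            assert after <= 0.2 * before, ch
        good = select_trials(events)
        truth = Recording(gt.clean.astype(float), FS, rec.ch_names,
                          rec.ch_types, montage)
        ev_t = average(epoch(truth, good, "response"))
        ev_c = average(epoch(cleaned, good, "response"))
        lp = sps.butter(4, 15, fs=FS, output="sos")
        for ch in ("FCz", "FC5"):
            a = sps.sosfiltfilt(lp, ev_c.channel(ch))
            b = sps.sosfiltfilt(lp, ev_t.channel(ch))
            assert np.corrcoef(a, b)[0, 1] >= 0.95, ch

    def test_clean_recording_essentially_unchanged(self, montage, head):
        """No EMG contamination: cleaning is near-identity per channel."""
        from speecherp import simulate_recording
        from speecherp.preprocess import highpass
        from speecherp.synth import ArtifactSpec, TrialSchedule, default_sources
        art = ArtifactSpec(emg_amplitude_uv=0.0, blink_rate_hz=0.0,
                           sensor_noise_rms_uv=0.0)
        rec, _, _ = simulate_recording(montage, head,
                                       default_sources(montage, head), art,
                                       TrialSchedule(n_trials=20, seed=31))
        filt = highpass(rec)
        out, _ = remove_emg(filt)
        scalp = [i for i, t in enumerate(rec.ch_types) if t == "eeg"]
        for i in scalp:
            assert np.corrcoef(out.data[i], filt.data[i])[0, 1] >= 0.99

    def test_cleaning_never_inflates_low_band_of_evoked(self, sim_full):
        from speecherp.preprocess import (average, epoch, highpass,
                                          ocular_correct, select_trials)
        rec, events, _ = sim_full
        filt, _ = ocular_correct(highpass(rec), events=events)
        cleaned, _ = remove_emg(filt)
        good = select_trials(events)
        ev_b = average(epoch(filt, good, "response"))
        ev_a = average(epoch(cleaned, good, "response"))
        scalp = ev_a.picks("eeg")
        p_before = sum(_band_power(ev_b.data[i], 0, 15) for i in scalp)
        p_after = sum(_band_power(ev_a.data[i], 0, 15) for i in scalp)
        assert p_after <= 1.05 * p_before

    def test_epoched_entry_point(self, sim_full):
        from speecherp.preprocess import epoch, select_trials
        rec, events, _ = sim_full
        good = select_trials(events).iloc[:5]
        # epochs must be longer than the channel count for the decomposition;
        # use the full 1.5 s maximum-trial-length window
        ep = epoch(rec, good, "response", window_ms=(-500.0, 1000.0),
                   baseline_ms=(-500.0, -300.0))
        out, report = remove_emg_epochs(ep)
        assert out.data.shape == ep.data.shape
        assert len(report) == ep.n_retained
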