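"""Filtering, ocular correction, epoching, rejection and averaging."""

import numpy as np
import pytest
from scipy import signal as sps

from speecherp.containers import Recording, make_event_table
from speecherp.preprocess import (average, epoch, highpass, ocular_correct,
                                  reject_artifacts, select_trials)

FS = 512.0


def _recording(data, ch_types=None):
    n = data.shape[0]
    names = [f"C{i}" for i in range(n)]
    types = ch_types or ["eeg"] * n
    return Recording(data, FS, names, types)


class TestHighpass:
    def test_removes_constant_offset(self):
        rec = _recording(np.full((2, 4096), 50.0))
        out = highpass(rec, 0.16)
        assert np.abs(out.data).max() < 0.5  # < 1% of the 50 µV offset

    def test_preserves_10hz_amplitude_within_1pct(self):
        t = np.arange(8192) / FS
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out = highpass(rec, 0.16)
        mid = slice(1024, -1024)
        assert abs(out.data[0, mid].std() / rec.data[0, mid].std() - 1) < 0.01

    def test_cutoff_out_of_range_raises(self):
        rec = _recording(np.zeros((1, 1024)))
        with pytest.raises(ValueError):
            highpass(rec, 300.0)
        with pytest.raises(ValueError):
            highpass(rec, 0.0)


class TestOcularCorrect:
    def _mixture(self, factor=0.3, seed=0, uncorrelated=False):
        rng = np.random.default_rng(seed)
        n = 60 * int(FS)
        sos = sps.butter(4, 12, fs=FS, output="sos")
        clean = sps.sosfiltfilt(sos, rng.standard_normal((3, n))) * 10
        blink_train = np.zeros(n)
        for c in rng.integers(500, n - 500, size=40):
            w = np.hanning(150) ** 2
            blink_train[c:c + 150] += w * rng.uniform(80, 120)
        eog = blink_train + rng.standard_normal(n)
        eeg = clean + (0.0 if uncorrelated else factor) * eog
        data = np.vstack([eeg, eog])
        rec = Recording(data, FS, ["C0", "C1", "C2", "VEOG"],
                        ["eeg"] * 3 + ["eog"])
        return rec, clean

    def test_recovers_known_propagation_factor(self):
        rec, clean = self._mixture(factor=0.3)
        out, b = ocular_correct(rec)
        assert np.allclose(b, 0.3, atol=0.02)
        for i in range(3):
            assert np.corrcoef(out.data[i], clean[i])[0, 1] >= 0.99

    def test_uncorrelated_eog_leaves_eeg_unchanged(self):
        rec, clean = self._mixture(uncorrelated=True)
        out, b = ocular_correct(rec)
        assert np.abs(b).max() < 0.02
        assert np.corrcoef(out.data[0], rec.data[0])[0, 1] > 0.999

    def test_zero_variance_eog_raises(self):
        data = np.vstack([np.random.default_rng(0).standard_normal((2, 1000)),
                          np.zeros((1, 1000))])
        rec = Recording(data, FS, ["C0", "C1", "VEOG"], ["eeg", "eeg", "eog"])
        with pytest.raises(ValueError, match="zero variance"):
            ocular_correct(rec)

    def test_missing_eog_channel_raises(self):
        rec = _recording(np.zeros((2, 1000)) + 1.0)
        with pytest.raises(ValueError, match="EOG"):
            ocular_correct(rec)


class TestSelectTrials:
    def test_counts(self):
        acc = (["correct"] * 7 + ["error"] * 2 + ["no_response"])
        stim = np.arange(10, dtype=float)
        voc = stim + 0.6
        voc[9] = np.nan
        ev = make_event_table(stim, voc, acc)
        out = select_trials(ev)
        assert len(out) == 7
        assert (out["accuracy"] == "correct").all()

    def test_all_correct_is_identity(self):
        ev = make_event_table([0.0, 2.0], [0.7, 2.7], ["correct", "correct"])
        assert len(select_trials(ev)) == 2

    def test_voicekey_fail_removed(self):
        ev = make_event_table([0.0, 2.0], [0.7, np.nan],
                              ["correct", "voicekey_fail"])
        out = select_trials(ev)
        assert list(out["trial_index"]) == [0]


class TestEpoch:
    def test_constant_channel_baselined_to_zero(self):
        rec = _recording(np.full((2, 4096), 5.0))
        ev = make_event_table([2.0], [2.6], ["correct"])
        ep = epoch(rec, ev, "stimulus")
        assert np.allclose(ep.data, 0.0)

    def test_time_zero_at_lock_event(self):
        data = np.zeros((1, 4096))
        data[0, 1024] = 1.0  # spike at exactly 2.0 s
        rec = _recording(data)
        ev = make_event_table([2.0], [2.6], ["correct"])
        ep = epoch(rec, ev, "stimulus", baseline_ms=(-200.0, -100.0))
        spike_t = ep.times_ms[np.argmax(ep.data[0, 0])]
        assert abs(spike_t) < 1000.0 / FS

    def test_response_lock_uses_vocal_onset(self):
        data = np.zeros((1, 4096))
        data[0, int(2.6 * FS)] = 1.0
        rec = _recording(data)
        ev = make_event_table([2.0], [2.6], ["correct"])
        ep = epoch(rec, ev, "response", baseline_ms=(-500.0, -300.0))
        spike_t = ep.times_ms[np.argmax(ep.data[0, 0])]
        assert abs(spike_t) < 1000.0 / FS

    def test_out_of_bounds_trial_dropped_with_reason(self):
        rec = _recording(np.zeros((1, 4096)))
        ev = make_event_table([0.05, 2.0], [0.65, 2.6], ["correct", "correct"])
        ep = epoch(rec, ev, "stimulus")
        assert ep.retained.tolist() == [False, True]
        assert ep.reject_reason[0] == "bounds"

    def test_baseline_correction_idempotent(self):
        rng = np.random.default_rng(4)
        rec = _recording(rng.standard_normal((3, 4096)))
        ev = make_event_table([2.0, 4.0], [2.6, 4.6], ["correct"] * 2)
        ep1 = epoch(rec, ev, "stimulus")
        bl = (ep1.times_ms >= -200.0) & (ep1.times_ms <= 0.0)
        again = ep1.data - ep1.data[:, :, bl].mean(axis=2, keepdims=True)
        assert np.allclose(again, ep1.data, atol=1e-12)

    def test_epoch_then_average_is_linear(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((2, 4096))
        b = rng.standard_normal((2, 4096))
        ev = make_event_table([2.0, 4.0], [2.6, 4.6], ["correct"] * 2)
        ev_a = average(epoch(_recording(a), ev, "stimulus"))
        ev_b = average(epoch(_recording(b), ev, "stimulus"))
        ev_ab = average(epoch(_recording(a + b), ev, "stimulus"))
        assert np.allclose(ev_ab.data, ev_a.data + ev_b.data, atol=1e-10)

    def test_zero_rt_variability_aligns_both_locks(self):
        """With constant RT the two locks are the same average, shifted."""
        rng = np.random.default_rng(8)
        data = rng.standard_normal((2, int(FS) * 30))
        rec = _recording(data)
        stim = np.arange(2.0, 26.0, 3.0)
        ev = make_event_table(stim, stim + 0.5, ["correct"] * len(stim))
        w = (-200.0, 200.0)
        bl = (-200.0, -100.0)
        es = average(epoch(rec, ev, "stimulus", w, bl))
        # response = stimulus + 500 ms exactly
        er = average(epoch(rec, ev, "response",
                           (w[0] - 500.0, w[1] - 500.0),
                           (bl[0] - 500.0, bl[1] - 500.0)))
        peak = np.abs(es.data).max()
        assert np.abs(es.data - er.data).max() < 1e-6 * peak


class TestRejectAndAverage:
    def _epochs(self, n_trials=10, amp=1.0, seed=0):
        rng = np.random.default_rng(seed)
        data = amp * rng.standard_normal((1, int(FS) * (3 * n_trials + 4)))
        rec = _recording(data)
        stim = np.arange(2.0, 2.0 + 3 * n_trials, 3.0)
        ev = make_event_table(stim, stim + 0.6, ["correct"] * n_trials)
        return rec, ev

    def test_clean_set_fully_retained(self):
        rec, ev = self._epochs()
        ep = reject_artifacts(epoch(rec, ev, "stimulus"), 150.0, 0.001)
        assert ep.n_retained == ep.n_trials

    def test_known_contaminated_trials_rejected_exactly(self):
        rec, ev = self._epochs(n_trials=20)
        bad = [3, 11]
        for b in bad:
            s = int(ev.loc[b, "stimulus_onset_s"] * FS)
            rec.data[0, s + 50:s + 80] += 500.0
        ep = reject_artifacts(epoch(rec, ev, "stimulus"), ptp_limit_uv=200.0,
                              flat_limit_uv=0.001, local_z=np.inf)
        rejected = np.nonzero(~ep.retained)[0].tolist()
        assert rejected == bad
        assert all(ep.reject_reason[b] == "ptp" for b in bad)

    def test_flat_trial_rejected_as_flat(self):
        rec, ev = self._epochs(n_trials=5)
        s = int(ev.loc[2, "stimulus_onset_s"] * FS)
        rec.data[0, s - 200:s + 500] = 0.0
        ep = reject_artifacts(epoch(rec, ev, "stimulus"), 150.0,
                              flat_limit_uv=0.01, local_z=np.inf)
        assert not ep.retained[2]
        assert ep.reject_reason[2] == "flat"

    def test_local_single_channel_outlier_rejected(self):
        rng = np.random.default_rng(1)
        n_tr = 20
        data = rng.standard_normal((4, int(FS) * (3 * n_tr + 4)))
        rec = _recording(data)
        stim = np.arange(2.0, 2.0 + 3 * n_tr, 3.0)
        ev = make_event_table(stim, stim + 0.6, ["correct"] * n_tr)
        s = int(stim[7] * FS)
        rec.data[2, s:s + 100] += 40.0  # big on one channel only
        ep = reject_artifacts(epoch(rec, ev, "stimulus"), 150.0, 0.001, 5.0)
        assert not ep.retained[7]
        assert ep.reject_reason[7] == "local"

    def test_average_of_identical_trials(self):
        rec, ev = self._epochs(n_trials=4, amp=0.0)
        ep = epoch(rec, ev, "stimulus")
        ep.data += 3.0  # identical post-baseline content
        ev_out = average(ep)
        assert np.allclose(ev_out.data, ep.data[0])
        assert ev_out.nave == 4

    def test_average_noise_scales_as_sqrt_n(self):
        rng = np.random.default_rng(2)
        n_tr = 1000
        data = rng.standard_normal((1, n_tr, 200))
        from speecherp.containers import EpochSet
        times = np.arange(200) / FS * 1000
        ep = EpochSet(data.transpose(1, 0, 2), times, FS, "stimulus",
                      (0.0, float(times[-1])), ["C0"], ["eeg"],
                      np.arange(n_tr))
        # baseline over the whole epoch: subtract means first, like epoch()
        ep.data -= ep.data.mean(axis=2, keepdims=True)
        rms_single = ep.data.std()
        rms_avg = average(ep).data.std()
        assert abs(rms_avg / (rms_single / np.sqrt(n_tr)) - 1) < 0.2

    def test_average_empty_raises(self):
        rec, ev = self._epochs(n_trials=3)
        ep = epoch(rec, ev, "stimulus")
        ep.retained[:] = False
        with pytest.raises(ValueError, match="no retained"):
            average(ep)

    def test_invalid_limits_raise(self):
        rec, ev = self._epochs(n_trials=3)
        with pytest.raises(ValueError):
            reject_artifacts(epoch(rec, ev, "stimulus"), -1.0, 0.1)
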