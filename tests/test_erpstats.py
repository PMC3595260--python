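"""GFP, analysis-window selection, slopes, peaks and latency-RT tests."""

import numpy as np
import pandas as pd
import pytest

from speecherp.containers import Evoked
from speecherp.erpstats import (AnalysisWindow, GfpCurve, gfp,
                                latency_rt_relation, peak_latency,
                                peak_to_peak_surface, rm_anova,
                                select_gfp_windows, slope_test)

FS = 512.0


def _evoked(data, lock="stimulus", t0_ms=0.0):
    data = np.atleast_2d(data)
    n_ch, n_t = data.shape
    times = t0_ms + np.arange(n_t) / FS * 1000.0
    return Evoked(data, times, FS, lock, 1, [f"C{i}" for i in range(n_ch)],
                  ["eeg"] * n_ch)


class TestGfp:
    def test_constant_map_is_zero(self):
        assert np.allclose(gfp(_evoked(np.full((5, 10), 3.3))).values, 0.0)

    def test_two_channel_plus_minus_one(self):
        ev = _evoked(np.array([[1.0], [-1.0]]))
        assert gfp(ev).values[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((64, 50))
        got = gfp(_evoked(x)).values
        expect = np.sqrt(((x - x.mean(axis=0)) ** 2).mean(axis=0))
        assert np.abs(got - expect).max() <= 1e-12

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 5))
        assert np.allclose(gfp(_evoked(x)).values,
                           gfp(_evoked(x + 42.0)).values)

    def test_single_channel_raises(self):
        with pytest.raises(ValueError):
            gfp(_evoked(np.ones((1, 10))))


class TestWindowSelection:
    def _curve(self, values, dt_ms=2.0):
        t = np.arange(len(values)) * dt_ms
        return GfpCurve(t, np.asarray(values, float))

    def test_monotone_ramp_selects_steepest_earliest(self):
        v = np.concatenate([np.zeros(50), np.arange(50) * 1.0,
                            np.full(50, 49.0)])
        wins = select_gfp_windows(self._curve(v), k=1, win_len_ms=20.0)
        assert len(wins) == 1
        # all interior ramp windows tie at the max slope; earliest wins
        assert wins[0].start_ms == pytest.approx(100.0)

    def test_three_bumps_give_three_rising_flanks(self):
        t = np.arange(0, 300, 2.0)
        v = np.zeros_like(t)
        for center, width, amp in ((80, 12, 1.0), (140, 12, 0.8),
                                   (200, 15, 1.2)):
            v += amp * np.exp(-((t - center) ** 2) / (2 * width**2))
        wins = select_gfp_windows(GfpCurve(t, v), k=3, win_len_ms=25.0)
        assert len(wins) == 3
        starts = [w.start_ms for w in wins]
        assert starts == sorted(starts)
        for w, center in zip(wins, (80, 140, 200)):
            # each window sits on the rising flank of its bump
            assert center - 35 <= w.start_ms <= center
            mid = (w.start_ms + w.end_ms) / 2
            assert v[np.searchsorted(t, w.end_ms)] > v[np.searchsorted(t, w.start_ms)]

    def test_requesting_more_windows_than_exist_warns(self):
        t = np.arange(0, 200, 2.0)
        v = (np.exp(-((t - 50) ** 2) / 100.0)
             + np.exp(-((t - 150) ** 2) / 100.0))
        with pytest.warns(UserWarning, match="only 2"):
            wins = select_gfp_windows(GfpCurve(t, v), k=5, win_len_ms=20.0)
        assert len(wins) == 2

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        v = np.abs(np.cumsum(rng.standard_normal(200)))
        c1 = select_gfp_windows(self._curve(v), k=2)
        c2 = select_gfp_windows(self._curve(v * 37.0), k=2)
        assert [(w.start_ms, w.end_ms) for w in c1] == \
            [(w.start_ms, w.end_ms) for w in c2]

    def test_windows_do_not_overlap(self):
        rng = np.random.default_rng(3)
        v = np.abs(np.cumsum(rng.standard_normal(300)))
        wins = select_gfp_windows(self._curve(v), k=3, win_len_ms=30.0)
        for a, b in zip(wins, wins[1:]):
            assert a.end_ms <= b.start_ms


class TestSlopeTest:
    def test_uniform_slope_is_degenerate(self):
        t = np.arange(100) / FS * 1000.0
        wf = np.tile(2.0 * t, (5, 1))
        res = slope_test(wf, t, AnalysisWindow(20.0, 80.0))
        assert np.allclose(res.slopes, 2.0)
        assert res.degenerate

    def test_baseline_offsets_do_not_change_result(self):
        rng = np.random.default_rng(4)
        t = np.arange(200) / FS * 1000.0
        wf = rng.standard_normal((8, 200))
        res1 = slope_test(wf, t, AnalysisWindow(50.0, 150.0))
        offsets = rng.standard_normal((8, 1)) * 100
        res2 = slope_test(wf + offsets, t, AnalysisWindow(50.0, 150.0))
        assert np.allclose(res1.slopes, res2.slopes)
        assert res1.t == pytest.approx(res2.t)

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(5)
        t = np.arange(100) / FS * 1000.0
        res = slope_test(rng.standard_normal((12, 100)), t,
                         AnalysisWindow(20.0, 170.0))
        assert res.df == 11

    def test_one_tailed_halves_two_tailed_p(self):
        rng = np.random.default_rng(6)
        t = np.arange(100) / FS * 1000.0
        wf = rng.standard_normal((6, 100))
        w = AnalysisWindow(20.0, 170.0)
        p2 = slope_test(wf, t, w, tail="two").p
        p1 = slope_test(wf, t, w, tail="one").p
        assert p1 == pytest.approx(p2 / 2)

    def test_too_few_subjects_raises(self):
        t = np.arange(100) / FS * 1000.0
        with pytest.raises(ValueError, match="3 subjects"):
            slope_test(np.zeros((2, 100)), t, AnalysisWindow(20.0, 80.0))


class TestPeakLatency:
    def _bump_evoked(self, center_ms, amp=-1.0, noise=0.0, seed=0,
                     n_t=512):
        rng = np.random.default_rng(seed)
        t = np.arange(n_t) / FS * 1000.0
        y = amp * np.exp(-((t - center_ms) ** 2) / (2 * 30.0**2))
        y = y + noise * rng.standard_normal(n_t)
        return _evoked(np.vstack([y, np.zeros_like(y)]))

    def test_noiseless_identical_subjects(self):
        grand = self._bump_evoked(300.0)
        subs = [self._bump_evoked(300.0) for _ in range(5)]
        pm = peak_latency(grand, subs, "C0", polarity="min")
        assert np.all(np.abs(pm.latencies_ms - 300.0) <= 1000.0 / FS)
        assert pm.grand_latency_ms == pytest.approx(300.0, abs=1000.0 / FS)

    def test_jittered_subjects_recovered(self):
        rng = np.random.default_rng(7)
        centers = 300.0 + rng.uniform(-20, 20, size=12)
        subs = [self._bump_evoked(c, noise=0.2, seed=i)
                for i, c in enumerate(centers)]
        grand = subs[0].copy()
        grand.data = np.mean([s.data for s in subs], axis=0)
        pm = peak_latency(grand, subs, "C0", polarity="min")
        err = np.abs(pm.latencies_ms - centers)
        assert np.quantile(err, 0.9) <= 10.0
        assert abs(pm.latencies_ms.mean() - 300.0) <= 5.0

    def test_flat_waveform_flagged_degenerate(self):
        grand = self._bump_evoked(300.0)
        flat = _evoked(np.zeros((2, 512)))
        with pytest.warns(UserWarning, match="flat"):
            pm = peak_latency(grand, [flat], "C0", polarity="min")
        assert pm.degenerate
        w0, w1 = pm.window_ms
        assert pm.latencies_ms[0] == pytest.approx((w0 + w1) / 2)

    def test_edge_extremum_flagged(self):
        grand = self._bump_evoked(300.0)
        ramp = _evoked(np.vstack([-np.arange(512.0), np.zeros(512)]))
        pm = peak_latency(grand, [ramp], "C0", polarity="min")
        assert pm.edge_flags[0]


class TestPeakToPeakSurface:
    def test_zero_signal(self):
        ev = _evoked(np.zeros((1, 512)))
        assert peak_to_peak_surface(ev, "C0", (200.0, 400.0)) == 0.0

    def test_rectangular_areas(self):
        # fine time grid so the 40 ms windows integrate the plateaus exactly
        t = np.arange(0.0, 600.0, 0.2)
        y = np.zeros_like(t)
        y[(t >= 175.0) & (t <= 225.0)] = 1.0
        y[(t >= 375.0) & (t <= 425.0)] = -1.0
        ev = Evoked(y[None, :], t, 5000.0, "stimulus", 1, ["C0"], ["eeg"])
        got = peak_to_peak_surface(ev, "C0", (200.0, 400.0), area_ms=40.0)
        assert got == pytest.approx((-40.0) - 40.0, rel=0.002)

    def test_half_sine_against_closed_form(self):
        t = np.arange(1024) / FS * 1000.0
        period = 40.0
        y = np.where((t >= 480.0) & (t <= 480.0 + period),
                     np.sin(np.pi * (t - 480.0) / period), 0.0)
        ev = _evoked(y)
        got = peak_to_peak_surface(ev, "C0", (100.0, 500.0), area_ms=40.0)
        exact = 2 * period / np.pi  # integral of sin over the half period
        assert got == pytest.approx(exact, rel=0.005)

    def test_window_beyond_epoch_raises(self):
        ev = _evoked(np.zeros((1, 100)))
        with pytest.raises(ValueError, match="epoch"):
            peak_to_peak_surface(ev, "C0", (5.0, 150.0))


class TestLatencyRt:
    def test_perfect_linear_relation(self):
        rts = np.array([600.0, 630.0, 660.0, 700.0, 720.0])
        lat = pd.DataFrame({"FCz": rts - 250.0})
        corr, model = latency_rt_relation(rts, lat)
        assert corr.loc[0, "rho"] == pytest.approx(1.0)
        assert corr.loc[0, "df"] == 3
        assert model.rsquared == pytest.approx(1.0)

    def test_constant_latencies_reported_as_undefined(self):
        rts = np.array([600.0, 630.0, 660.0, 700.0])
        corr, _ = latency_rt_relation(rts, pd.DataFrame({"Cz": [1.0] * 4}))
        assert np.isnan(corr.loc[0, "rho"])

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="4 subjects"):
            latency_rt_relation(np.array([1.0, 2.0, 3.0]),
                                pd.DataFrame({"Cz": [1.0, 2.0, 3.0]}))


class TestRmAnova:
    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n, k = 12, 4
        y = rng.standard_normal((n, k)) + np.linspace(0, 1, k)
        got = rm_anova(y)
        df = pd.DataFrame({
            "y": y.ravel(),
            "subject": np.repeat(np.arange(n), k),
            "level": np.tile(np.arange(k), n),
        })
        ref = pingouin.rm_anova(data=df, dv="y", within="level",
                                subject="subject").iloc[0]
        assert got["F"] == pytest.approx(float(ref["F"]), rel=1e-9)
        assert got["p"] == pytest.approx(float(ref["p_unc"]), rel=1e-9)
        assert (got["df1"], got["df2"]) == (int(ref["ddof1"]),
                                            int(ref["ddof2"]))
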