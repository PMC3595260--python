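"""Component statistics on averaged waveforms.

Covers the measurement conventions of the dual-locked analysis:

* global field power (GFP) — the spatial standard deviation across scalp
  channels at each time sample, a reference-free index of map strength;
* data-driven analysis windows at the fastest GFP increases;
* per-subject regression slopes within a window, tested against zero;
* peak latencies measured per subject inside a fixed window centered on
  the grand-average peak, on 40 ms moving-average smoothed data;
* baseline-independent peak-to-peak *surface* amplitudes: signed areas
  under the unsmoothed curve in 40 ms windows centered on two
  consecutive peaks, second minus first;
* per-electrode latency-RT correlations plus one grouped regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Evoked

__all__ = [
    "GfpCurve",
    "AnalysisWindow",
    "SlopeResult",
    "PeakMeasure",
    "gfp",
    "select_gfp_windows",
    "slope_test",
    "peak_latency",
    "peak_to_peak_surface",
    "latency_rt_relation",
    "rm_anova",
]


@dataclass
class GfpCurve:
    times_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, float)
        self.values = np.asarray(self.values, float)


@dataclass(frozen=True)
class AnalysisWindow:
    start_ms: float
    end_ms: float
    rank: int = 0

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")


@dataclass
class SlopeResult:
    slopes: np.ndarray  # per subject, units/ms
    t: float
    df: int
    p: float
    tail: str
    degenerate: bool = False


@dataclass
class PeakMeasure:
    electrode: str
    latencies_ms: np.ndarray  # per subject
    polarity: str
    window_ms: tuple
    grand_latency_ms: float
    edge_flags: np.ndarray = None
    degenerate: bool = False


def gfp(ev: Evoked) -> GfpCurve:
    """Global field power: spatial SD across scalp channels per sample."""
    scalp = ev.picks("eeg")
    if scalp.size < 2:
        raise ValueError("GFP needs at least 2 scalp channels")
    x = ev.data[scalp]
    return GfpCurve(ev.times_ms.copy(), x.std(axis=0, ddof=0))


def _sliding_slopes(y: np.ndarray, w: int) -> np.ndarray:
    """OLS slope of y against sample index in every length-w window."""
    from numpy.lib.stride_tricks import sliding_window_view

    t = np.arange(w, dtype=float)
    t -= t.mean()
    denom = (t**2).sum()
    win = sliding_window_view(y, w)
    return (win - win.mean(axis=1, keepdims=True)) @ t / denom


def select_gfp_windows(
    curve: GfpCurve,
    k: int = 3,
    win_len_ms: float = 25.0,
    t_min_ms: float | None = None,
) -> list:
    """Windows of fastest GFP increase.

    A window of ``win_len_ms`` slides sample by sample over the curve
    (restricted to ``t >= t_min_ms`` if given); its score is the OLS
    slope of the GFP inside it.  The ``k`` highest-scoring strictly
    positive-slope windows that do not overlap are returned ordered by
    onset.  Ties go to the earlier window.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    times = curve.times_ms
    vals = curve.values
    if t_min_ms is not None:
        sel = times >= t_min_ms
        times, vals = times[sel], vals[sel]
    dt = np.median(np.diff(times))
    w = max(int(round(win_len_ms / dt)) + 1, 2)
    if vals.size < w:
        raise ValueError("curve shorter than the window length")
    slopes = _sliding_slopes(vals, w)
    order = np.lexsort((np.arange(slopes.size), -slopes))  # desc, earliest first
    chosen = []
    taken = np.zeros(slopes.size, bool)
    for i in order:
        if len(chosen) == k:
            break
        if slopes[i] <= 0 or taken[i]:
            continue
        lo, hi = max(0, i - w + 1), min(slopes.size, i + w)
        if taken[max(0, i - w + 1):min(slopes.size, i + w)].any():
            continue
        taken[lo:hi] = True
        chosen.append(i)
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} qualifying GFP windows found (requested {k})",
            stacklevel=2,
        )
    chosen.sort()
    return [
        AnalysisWindow(start_ms=float(times[i]), end_ms=float(times[i + w - 1]),
                       rank=r)
        for r, i in enumerate(chosen)
    ]


def slope_test(
    subject_waveforms: np.ndarray,
    times_ms: np.ndarray,
    window: AnalysisWindow,
    tail: str = "two",
) -> SlopeResult:
    """Per-subject OLS slopes in a window, t-tested against zero.

    ``subject_waveforms`` is (n_subjects, n_times) for a single channel.
    Slopes are in input-units per ms and independent of any baseline
    (adding a constant per subject leaves them unchanged).  ``tail`` is
    ``"two"`` or ``"one"``; the one-tailed test takes the direction of
    the observed mean slope sign as the alternative — with the
    convention used here for expected negativities, a one-tailed test of
    negative slopes halves the p value when the mean slope is negative.
    """
    wf = np.asarray(subject_waveforms, float)
    times_ms = np.asarray(times_ms, float)
    if wf.ndim != 2 or wf.shape[0] < 3:
        raise ValueError("need >= 3 subjects (rows)")
    sel = (times_ms >= window.start_ms) & (times_ms <= window.end_ms)
    if sel.sum() < 2:
        raise ValueError("window does not cover at least 2 samples")
    t = times_ms[sel]
    tc = t - t.mean()
    denom = (tc**2).sum()
    y = wf[:, sel]
    slopes = (y - y.mean(axis=1, keepdims=True)) @ tc / denom
    n = slopes.size
    sd = slopes.std(ddof=1)
    degenerate = sd == 0.0
    if degenerate:
        tstat = np.inf if slopes.mean() != 0 else 0.0
        p = 0.0 if slopes.mean() != 0 else 1.0
    else:
        tstat = slopes.mean() / (sd / np.sqrt(n))
        if tail == "two":
            p = 2.0 * stats.t.sf(abs(tstat), n - 1)
        elif tail == "one":
            p = stats.t.sf(abs(tstat), n - 1)
        else:
            raise ValueError("tail must be 'one' or 'two'")
    return SlopeResult(slopes=slopes, t=float(tstat), df=n - 1, p=float(p),
                       tail=tail, degenerate=degenerate)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with shrinking symmetric edge windows."""
    kern = np.ones(w)
    num = np.convolve(x, kern, mode="same")
    den = np.convolve(np.ones_like(x), kern, mode="same")
    return num / den


def peak_latency(
    grand: Evoked,
    subjects: list,
    electrode: str,
    polarity: str = "min",
    search_ms: tuple | None = None,
    ga_window_ms: float = 100.0,
    smooth_ms: float = 40.0,
) -> PeakMeasure:
    """Per-subject peak latencies inside a grand-average-defined window.

    1. Find the ``polarity`` extremum of the grand average at
       ``electrode`` (optionally restricted to ``search_ms``).
    2. Center a ``ga_window_ms`` window on it.
    3. Per subject, smooth with a centered ``smooth_ms`` moving average
       and take the extremum latency within the window (earliest sample
       wins ties).

    A flat (all-zero) window is flagged degenerate and reported at the
    window center; subject extrema sitting on a window edge are flagged.
    """
    if polarity not in ("min", "max"):
        raise ValueError("polarity must be 'min' or 'max'")
    times = grand.times_ms
    g = grand.channel(electrode)
    sel = np.ones(times.size, bool)
    if search_ms is not None:
        sel = (times >= search_ms[0]) & (times <= search_ms[1])
    fn = np.argmin if polarity == "min" else np.argmax
    gsel = np.nonzero(sel)[0]
    g_peak_idx = gsel[fn(g[gsel])]
    g_lat = times[g_peak_idx]
    w0, w1 = g_lat - ga_window_ms / 2.0, g_lat + ga_window_ms / 2.0
    wsel = np.nonzero((times >= w0) & (times <= w1))[0]

    dt = np.median(np.diff(times))
    w_smooth = max(int(round(smooth_ms / dt)) | 1, 1)  # odd length
    lats, edges = [], []
    degenerate = False
    for ev in subjects:
        y = _moving_average(ev.channel(electrode), w_smooth)
        yw = y[wsel]
        if np.allclose(yw, 0.0):
            degenerate = True
            lats.append((w0 + w1) / 2.0)
            edges.append(False)
            continue
        i = wsel[fn(yw)]
        lats.append(times[i])
        edges.append(i == wsel[0] or i == wsel[-1])
    if degenerate:
        warnings.warn("flat waveform in peak window; latency set to window "
                      "center", stacklevel=2)
    return PeakMeasure(
        electrode=electrode, latencies_ms=np.asarray(lats, float),
        polarity=polarity, window_ms=(float(w0), float(w1)),
        grand_latency_ms=float(g_lat),
        edge_flags=np.asarray(edges, bool), degenerate=degenerate,
    )


def peak_to_peak_surface(
    subject: Evoked,
    electrode: str,
    latencies_ms: tuple,
    area_ms: float = 40.0,
) -> float:
    """Signed-area peak-to-peak amplitude (units·ms), second minus first.

    Integrates the *unsmoothed* waveform between the curve and the zero
    line over ``area_ms``-long windows centered on two consecutive peak
    latencies, and returns area(second) - area(first).  This measure is
    independent of the chosen baseline offset convention only up to the
    shared window length; its purpose is comparing rise amplitudes of
    consecutive deflections.
    """
    lat_a, lat_b = latencies_ms
    times = subject.times_ms
    y = subject.channel(electrode)
    areas = []
    for lat in (lat_a, lat_b):
        w0, w1 = lat - area_ms / 2.0, lat + area_ms / 2.0
        if w0 < times[0] or w1 > times[-1]:
            raise ValueError("surface window exceeds the epoch bounds")
        sel = (times >= w0) & (times <= w1)
        areas.append(np.trapezoid(y[sel], times[sel]))
    return float(areas[1] - areas[0])


def latency_rt_relation(
    rts_ms: np.ndarray,
    latencies_ms: pd.DataFrame,
):
    """Across-subject latency-RT correlations and grouped regression.

    Parameters
    ----------
    rts_ms : array (n_subjects,)
        Mean RT per subject.
    latencies_ms : DataFrame (n_subjects x n_electrodes)
        Per-subject peak latencies, one column per electrode.

    Returns
    -------
    (DataFrame, RegressionResults)
        Per-electrode Pearson rho with its t test (df = n - 2), and one
        multiple regression of RT on all electrode latencies
        (statsmodels OLS).
    """
    import statsmodels.api as sm

    rts = np.asarray(rts_ms, float)
    n = rts.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if latencies_ms.shape[0] != n:
        raise ValueError("latency table row count must match subjects")
    rows = []
    for col in latencies_ms.columns:
        lat = latencies_ms[col].to_numpy(float)
        if np.ptp(lat) == 0.0 or np.ptp(rts) == 0.0:
            rows.append({"electrode": col, "rho": np.nan, "t": np.nan,
                         "df": n - 2, "p": np.nan})
            continue
        rho, p = stats.pearsonr(lat, rts)
        with np.errstate(divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        rows.append({"electrode": col, "rho": float(rho), "t": float(tstat),
                     "df": n - 2, "p": float(p)})
    corr = pd.DataFrame(rows)
    X = sm.add_constant(latencies_ms.to_numpy(float))
    model = sm.OLS(rts, X).fit()
    return corr, model


def rm_anova(data: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA.

    ``data`` is (n_subjects, n_levels); the error term is the
    subject-by-factor interaction, i.e. F = MS_factor / MS_interaction
    with df = (k - 1, (n - 1)(k - 1)).
    """
    y = np.asarray(data, float)
    n, k = y.shape
    grand = y.mean()
    subj_m = y.mean(axis=1, keepdims=True)
    fact_m = y.mean(axis=0, keepdims=True)
    ss_factor = n * ((fact_m - grand) ** 2).sum()
    resid = y - subj_m - fact_m + grand
    ss_inter = (resid**2).sum()
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_factor = ss_factor / df1
    ms_inter = ss_inter / df2
    F = ms_factor / ms_inter
    p = stats.f.sf(F, df1, df2)
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p)}
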