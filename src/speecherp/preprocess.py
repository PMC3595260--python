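"""Filtering, ocular correction, trial selection, dual-lock epoching,
artifact rejection and averaging.

The processing order follows the standard sequence for this kind of
analysis: high-pass filter, regression-based ocular correction, (EMG
removal, see :mod:`speecherp.emgcca`), epoching to stimulus and to vocal
onset, automated artifact rejection, per-subject averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet, Evoked, Recording

__all__ = [
    "highpass",
    "ocular_correct",
    "select_trials",
    "epoch",
    "reject_artifacts",
    "average",
    "STIM_WINDOW_MS",
    "STIM_BASELINE_MS",
    "RESP_WINDOW_MS",
    "RESP_BASELINE_MS",
]

#: default analysis windows (ms relative to the lock event)
STIM_WINDOW_MS = (-200.0, 700.0)
STIM_BASELINE_MS = (-200.0, 0.0)
RESP_WINDOW_MS = (-500.0, 200.0)
RESP_BASELINE_MS = (-500.0, -300.0)


def highpass(rec: Recording, cutoff_hz: float = 0.16, order: int = 2) -> Recording:
    """Zero-phase Butterworth high-pass (forward-backward).

    The default 0.16 Hz cutoff removes drift while leaving the slow
    pre-response ramps untouched in phase (the filter is applied forward
    and backward, doubling the effective order).
    """
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, fs/2)")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return out


def ocular_correct(
    rec: Recording,
    eog_channels: list | None = None,
    events: pd.DataFrame | None = None,
    fs_window_ms: tuple = (-200.0, 700.0),
):
    """Regression-based ocular correction.

    Propagation factors from each EOG channel into each EEG channel are
    estimated by least squares and the scaled EOG is subtracted from the
    EEG.  When an event table is supplied, the stimulus-locked average is
    first subtracted from every trial of both EEG and EOG before the
    regression, so that event-related brain activity does not bias the
    factors (the classic refinement of the regression method); the
    correction itself is then applied to the raw signals.

    Returns
    -------
    (Recording, ndarray)
        Corrected recording and the (n_eog, n_eeg) propagation factors.
    """
    if eog_channels is None:
        eog_idx = rec.picks("eog")
    else:
        eog_idx = np.array([rec.index(c) for c in eog_channels])
    if eog_idx.size == 0:
        raise ValueError("no EOG channel available for ocular correction")
    eeg_idx = rec.picks("eeg")

    eeg = rec.data[eeg_idx]
    eog = rec.data[eog_idx]
    eeg_res, eog_res = eeg, eog
    if events is not None and len(events):
        eeg_res = eeg - _event_locked_average_signal(eeg, events, rec.fs,
                                                     fs_window_ms)
        eog_res = eog - _event_locked_average_signal(eog, events, rec.fs,
                                                     fs_window_ms)
    eog_var = eog_res.var(axis=1)
    if np.any(eog_var <= 0):
        raise ValueError("EOG channel with zero variance")
    eogc = eog_res - eog_res.mean(axis=1, keepdims=True)
    eegc = eeg_res - eeg_res.mean(axis=1, keepdims=True)
    # b solves EOG' b = EEG' in the least-squares sense
    b, *_ = np.linalg.lstsq(eogc.T, eegc.T, rcond=None)  # (n_eog, n_eeg)
    out = rec.copy()
    out.data[eeg_idx] = eeg - b.T @ eog
    return out, b


def _event_locked_average_signal(x, events, fs, window_ms):
    """Continuous signal holding the stimulus-locked average at each trial."""
    i0 = int(round(window_ms[0] / 1000.0 * fs))
    i1 = int(round(window_ms[1] / 1000.0 * fs))
    n = x.shape[1]
    segs = []
    starts = []
    for onset in events["stimulus_onset_s"].to_numpy():
        s = int(round(onset * fs)) + i0
        if s >= 0 and s + (i1 - i0) <= n:
            segs.append(x[:, s:s + (i1 - i0)])
            starts.append(s)
    avg_sig = np.zeros_like(x)
    if not segs:
        return avg_sig
    erp = np.mean(segs, axis=0)
    for s in starts:
        avg_sig[:, s:s + erp.shape[1]] = erp
    return avg_sig


def select_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only correct trials that have a vocal onset."""
    keep = (events["accuracy"] == "correct") & events["vocal_onset_s"].notna()
    return events.loc[keep].reset_index(drop=True)


def epoch(
    rec: Recording,
    events: pd.DataFrame,
    lock: str,
    window_ms: tuple | None = None,
    baseline_ms: tuple | None = None,
) -> EpochSet:
    """Cut trials time-locked to the stimulus or to vocal onset.

    Time 0 of each epoch sits at the lock event; the per-channel mean over
    the baseline window is subtracted trial by trial.  Trials whose epoch
    would exceed the recording bounds (or, for response locking, that lack
    a vocal onset) are kept in the container but masked out with a reason.
    """
    if lock == "stimulus":
        window_ms = window_ms or STIM_WINDOW_MS
        baseline_ms = baseline_ms or STIM_BASELINE_MS
        anchors = events["stimulus_onset_s"].to_numpy()
    elif lock == "response":
        window_ms = window_ms or RESP_WINDOW_MS
        baseline_ms = baseline_ms or RESP_BASELINE_MS
        anchors = events["vocal_onset_s"].to_numpy()
    else:
        raise ValueError("lock must be 'stimulus' or 'response'")
    if len(events) == 0:
        raise ValueError("no events to epoch")
    if not (window_ms[0] <= baseline_ms[0] < baseline_ms[1] <= window_ms[1]):
        raise ValueError("baseline window must lie inside the epoch window")

    fs = rec.fs
    # outward rounding so the realized window always covers the request
    i0 = int(np.floor(window_ms[0] / 1000.0 * fs))
    i1 = int(np.ceil(window_ms[1] / 1000.0 * fs))
    times_ms = np.arange(i0, i1 + 1) / fs * 1000.0
    n_t = times_ms.size
    n_tr = len(events)
    data = np.zeros((n_tr, rec.n_channels, n_t))
    retained = np.ones(n_tr, bool)
    reasons = [""] * n_tr
    for k, anchor in enumerate(anchors):
        if not np.isfinite(anchor):
            retained[k] = False
            reasons[k] = "no_lock_event"
            continue
        c = int(round(anchor * fs))
        if c + i0 < 0 or c + i1 + 1 > rec.n_samples:
            retained[k] = False
            reasons[k] = "bounds"
            continue
        data[k] = rec.data[:, c + i0: c + i1 + 1]
    bl = (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])
    data -= data[:, :, bl].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data, times_ms=times_ms, fs=fs, lock=lock,
        baseline_ms=tuple(baseline_ms), ch_names=list(rec.ch_names),
        ch_types=list(rec.ch_types),
        trial_index=events["trial_index"].to_numpy(),
        retained=retained, reject_reason=reasons,
    )


def reject_artifacts(
    ep: EpochSet,
    ptp_limit_uv: float = 150.0,
    flat_limit_uv: float = 0.5,
    local_z: float = 5.0,
) -> EpochSet:
    """Automated surrogate for trial-by-trial visual inspection.

    Three rules, applied to scalp channels of currently-retained trials:

    * global: any-channel peak-to-peak above ``ptp_limit_uv`` (gross
      artifact);
    * flat: all channels peak-to-peak below ``flat_limit_uv`` (dead
      recording);
    * local: a single channel whose peak-to-peak is an outlier across
      trials (robust z-score — median/MAD, so one gross trial cannot mask
      itself — above ``local_z``): the surface Laplacian is very
      sensitive to small single-electrode artifacts, so these trials are
      dropped too.
    """
    if ptp_limit_uv <= 0 or flat_limit_uv <= 0:
        raise ValueError("rejection limits must be positive")
    out = ep.copy()
    scalp = out.picks("eeg")
    ptp = out.data[:, scalp, :].max(axis=2) - out.data[:, scalp, :].min(axis=2)
    active = out.retained.copy()
    for k in np.nonzero(active)[0]:
        if ptp[k].max() > ptp_limit_uv:
            out.retained[k] = False
            out.reject_reason[k] = "ptp"
        elif ptp[k].max() < flat_limit_uv:
            out.retained[k] = False
            out.reject_reason[k] = "flat"
    # local single-channel outliers, robust-z-scored across surviving trials
    surv = np.nonzero(out.retained)[0]
    if surv.size >= 3 and np.isfinite(local_z):
        p = ptp[surv]
        med = np.median(p, axis=0)
        # scale floor at 10% of the typical amplitude: with few trials the
        # MAD itself is noisy and would otherwise flag ordinary variation
        scale = np.maximum(np.median(np.abs(p - med), axis=0) * 1.4826,
                           0.1 * med)
        scale = np.where(scale > 0, scale, np.inf)
        z = (p - med) / scale
        for j, k in enumerate(surv):
            if z[j].max() > local_z:
                out.retained[k] = False
                out.reject_reason[k] = "local"
    return out


def average(ep: EpochSet) -> Evoked:
    """Arithmetic mean over retained trials."""
    if ep.n_retained < 1:
        raise ValueError("no retained trials to average")
    return Evoked(
        data=ep.retained_data().mean(axis=0),
        times_ms=ep.times_ms.copy(), fs=ep.fs, lock=ep.lock,
        nave=ep.n_retained, ch_names=list(ep.ch_names),
        ch_types=list(ep.ch_types), units=ep.units,
    )
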