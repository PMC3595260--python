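"""Blind source separation by canonical correlation (BSS-CCA) for EMG
artifact removal.

The decomposition solves the canonical correlation problem between the
multichannel signal X(t) and its one-sample delay X(t-1).  Because the
canonical correlations equal the lag-1 autocorrelations of the extracted
components, sorting components by canonical correlation separates smooth,
highly autocorrelated brain activity from broadband, weakly
autocorrelated muscle activity.  Components are classified by the ratio
of their average spectral power in the EMG band (15-30 Hz) to that in the
EEG band (0-15 Hz); a component is EMG whenever that ratio reaches 1/5.
Removal operates on non-overlapping windows (default 1.5 s, the maximum
trial length) so that local articulation bursts are targeted rather than
tonic muscle tone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import signal as sps

from .containers import EpochSet, Recording

__all__ = [
    "CcaDecomposition",
    "ComponentClass",
    "cca_decompose",
    "classify_components",
    "remove_emg",
    "remove_emg_epochs",
    "EEG_BAND_HZ",
    "EMG_BAND_HZ",
    "DEFAULT_RATIO_THRESHOLD",
]

logger = logging.getLogger(__name__)

EEG_BAND_HZ = (0.0, 15.0)
EMG_BAND_HZ = (15.0, 30.0)
DEFAULT_RATIO_THRESHOLD = 1.0 / 5.0
_SHRINKAGE = 1e-3  # covariance shrinkage, as a fraction of trace / n_ch


@dataclass
class CcaDecomposition:
    """Result of one window's CCA decomposition.

    ``unmixing`` (components x channels) applied to the centered data
    yields unit-variance component time courses; ``mixing`` (channels x
    components) back-projects them.  ``autocorr`` holds the canonical
    correlations (= lag-1 component autocorrelations), non-increasing.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    components: np.ndarray
    autocorr: np.ndarray
    mean: np.ndarray

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Back-project (a subset of) components to channel space."""
        if keep is None:
            keep = np.ones(self.components.shape[0], bool)
        keep = np.asarray(keep, bool)
        return self.mixing[:, keep] @ self.components[keep] + self.mean


@dataclass
class ComponentClass:
    """Band powers and EMG/EEG label of one component."""

    index: int
    eeg_power: float
    emg_power: float
    ratio: float
    label: str  # "EEG" or "EMG"


def cca_decompose(X: np.ndarray) -> CcaDecomposition:
    """CCA between a window and its one-sample delay.

    Parameters
    ----------
    X : ndarray (n_channels, n_samples)
        One analysis window; needs more samples than channels.

    Notes
    -----
    Solves the generalized eigenproblem
    ``C_ab C_bb^{-1} C_ba w = rho^2 C_aa w`` with A = X(t), B = X(t-1).
    A shrinkage ridge (``1e-3 * trace / n_ch`` by default) is always
    added to the covariance diagonals: with 64+ channels in a 1.5 s
    window the sample covariance is noisy, and unshrunk CCA manufactures
    spurious low-autocorrelation directions out of estimation noise.  A
    much larger ridge is substituted, with a logged warning, when the
    covariance is numerically rank deficient.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be (n_channels, n_samples)")
    n_ch, n_s = X.shape
    if n_s <= n_ch:
        raise ValueError("need more samples than channels")
    if not np.any(X != 0):
        raise ValueError("all-zero window")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    A = Xc[:, 1:]
    B = Xc[:, :-1]
    n = A.shape[1]
    Caa = A @ A.T / n
    Cbb = B @ B.T / n
    Cab = A @ B.T / n
    tr = np.trace(Caa)
    eps = _SHRINKAGE * tr / n_ch
    if np.linalg.eigvalsh(Caa)[0] < 1e-10 * tr / n_ch:
        eps = max(eps, 1e-6 * tr / n_ch)
        logger.warning("rank-deficient window covariance; ridge %.3e applied",
                       eps)
    Caa = Caa + eps * np.eye(n_ch)
    Cbb = Cbb + eps * np.eye(n_ch)
    M = Cab @ np.linalg.solve(Cbb, Cab.T)
    rho2, W = sla.eigh((M + M.T) / 2.0, Caa)  # ascending
    order = np.argsort(rho2)[::-1]
    rho = np.sqrt(np.clip(rho2[order], 0.0, 1.0))
    W = W[:, order]  # columns: unmixing directions, w' Caa w = 1
    comps = W.T @ Xc
    sd = comps.std(axis=1, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    comps /= sd[:, None]
    unmixing = W.T / sd[:, None]
    mixing = np.linalg.pinv(unmixing)
    return CcaDecomposition(unmixing=unmixing, mixing=mixing, components=comps,
                            autocorr=rho, mean=mean)


def classify_components(
    dec: CcaDecomposition,
    fs: float,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list:
    """Label each component EEG or EMG from its Welch band-power ratio.

    Average power is computed in the EEG band [0, 15) Hz and the EMG band
    [15, 30] Hz (Welch: 1 s Hann segments, 50% overlap); a component is
    EMG iff ``emg_power / eeg_power >= ratio_threshold``.
    """
    if fs <= 60:
        raise ValueError("sampling rate too low for the 0-15/15-30 Hz bands")
    nper = int(min(fs, dec.components.shape[1]))
    f, psd = sps.welch(dec.components, fs=fs, window="hann", nperseg=nper,
                       noverlap=nper // 2, axis=1)
    eeg_band = (f >= EEG_BAND_HZ[0]) & (f < EEG_BAND_HZ[1])
    emg_band = (f >= EMG_BAND_HZ[0]) & (f <= EMG_BAND_HZ[1])
    out = []
    for i in range(psd.shape[0]):
        p_eeg = float(psd[i, eeg_band].mean())
        p_emg = float(psd[i, emg_band].mean())
        if p_eeg == 0.0:
            logger.warning("component %d: zero EEG-band power; ratio = inf", i)
            ratio = np.inf
        else:
            ratio = p_emg / p_eeg
        label = "EMG" if ratio >= ratio_threshold else "EEG"
        out.append(ComponentClass(index=i, eeg_power=p_eeg, emg_power=p_emg,
                                  ratio=ratio, label=label))
    return out


def _clean_window(X, fs, ratio_threshold):
    dec = cca_decompose(X)
    classes = classify_components(dec, fs, ratio_threshold)
    is_emg = np.array([c.label == "EMG" for c in classes])
    # subtract the flagged components (identical to rebuilding from the
    # kept ones in the full-rank case, but exact when nothing is flagged)
    cleaned = X - dec.mixing[:, is_emg] @ dec.components[is_emg]
    ratios = [c.ratio for c, e in zip(classes, is_emg) if e]
    return cleaned, int(is_emg.sum()), float(np.mean(ratios)) if ratios else np.nan


def remove_emg(
    rec: Recording,
    window_s: float = 1.5,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
):
    """Window-wise BSS-CCA cleaning of a continuous recording.

    The recording is split into non-overlapping windows of ``window_s``
    seconds; in each window the CCA components classified as EMG are
    zeroed and the rest back-projected.  A trailing partial window is
    processed on its own when long enough for the decomposition (more
    samples than channels), otherwise it is merged into the preceding
    window.

    Returns
    -------
    (Recording, DataFrame)
        Cleaned recording and a per-window report with columns
        ``window_index, start_s, n_components_removed, mean_ratio_removed``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win_samp = int(round(window_s * rec.fs))
    n = rec.n_samples
    if n < n_win_samp:
        raise ValueError("recording shorter than one window")
    n_ch = rec.n_channels
    edges = list(range(0, n - n_win_samp + 1, n_win_samp))
    bounds = [(s, s + n_win_samp) for s in edges]
    rem = n - bounds[-1][1]
    if rem > 0:
        if rem > n_ch + 1:
            bounds.append((bounds[-1][1], n))
        else:  # too short to decompose: merge into the last full window
            bounds[-1] = (bounds[-1][0], n)
    out = rec.copy()
    rows = []
    for w, (s, e) in enumerate(bounds):
        cleaned, n_rm, mean_ratio = _clean_window(rec.data[:, s:e], rec.fs,
                                                  ratio_threshold)
        out.data[:, s:e] = cleaned
        rows.append({"window_index": w, "start_s": s / rec.fs,
                     "n_components_removed": n_rm,
                     "mean_ratio_removed": mean_ratio})
    return out, pd.DataFrame(rows)


def remove_emg_epochs(
    ep: EpochSet,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
):
    """Apply BSS-CCA cleaning epoch by epoch (each epoch is one window)."""
    out = ep.copy()
    rows = []
    for k in range(ep.n_trials):
        if not ep.retained[k]:
            continue
        cleaned, n_rm, mean_ratio = _clean_window(ep.data[k], ep.fs,
                                                  ratio_threshold)
        out.data[k] = cleaned
        rows.append({"window_index": k, "start_s": np.nan,
                     "n_components_removed": n_rm,
                     "mean_ratio_removed": mean_ratio})
    return out, pd.DataFrame(rows)
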