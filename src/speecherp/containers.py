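"""In-memory containers shared across pipeline stages.

An :class:`EventTable` is a plain :class:`pandas.DataFrame` with one row
per trial and the columns

``trial_index``     int, 0-based
``stimulus_onset_s`` float, seconds from recording start
``vocal_onset_s``   float or NaN (absent response)
``accuracy``        one of ``correct | error | no_response | voicekey_fail``

Reaction time in ms is ``(vocal_onset_s - stimulus_onset_s) * 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACCURACY_CODES",
    "Recording",
    "EpochSet",
    "Evoked",
    "make_event_table",
    "rt_ms",
]

ACCURACY_CODES = ("correct", "error", "no_response", "voicekey_fail")


def make_event_table(stimulus_onset_s, vocal_onset_s, accuracy) -> pd.DataFrame:
    """Assemble and validate an event table from per-trial arrays."""
    df = pd.DataFrame(
        {
            "trial_index": np.arange(len(stimulus_onset_s)),
            "stimulus_onset_s": np.asarray(stimulus_onset_s, float),
            "vocal_onset_s": np.asarray(vocal_onset_s, float),
            "accuracy": list(accuracy),
        }
    )
    bad = ~df["accuracy"].isin(ACCURACY_CODES)
    if bad.any():
        raise ValueError(f"unknown accuracy codes: {set(df.loc[bad, 'accuracy'])}")
    has_vo = df["vocal_onset_s"].notna()
    if (df.loc[has_vo, "vocal_onset_s"] <= df.loc[has_vo, "stimulus_onset_s"]).any():
        raise ValueError("vocal onset must follow stimulus onset")
    return df


def rt_ms(events: pd.DataFrame) -> np.ndarray:
    """Per-trial reaction times in ms (NaN where no vocal onset)."""
    return (events["vocal_onset_s"] - events["stimulus_onset_s"]).to_numpy() * 1000.0


@dataclass
class Recording:
    """Continuous multichannel recording in µV.

    ``data`` has shape (n_channels, n_samples); ``ch_types`` entries are
    ``"eeg"`` or ``"eog"``.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    ch_types: list[str]
    montage: object = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data")
        if len(self.ch_types) != self.data.shape[0]:
            raise ValueError("ch_types length does not match data")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def picks(self, ch_type: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == ch_type],
                        dtype=int)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.ch_names),
                         list(self.ch_types), self.montage)


@dataclass
class EpochSet:
    """Trials x channels x time array with lock and baseline metadata.

    ``lock`` is ``"stimulus"`` or ``"response"``; ``times_ms`` is relative
    to the lock event; ``retained`` masks trials surviving rejection, with
    a human-readable ``reject_reason`` per dropped trial.
    """

    data: np.ndarray
    times_ms: np.ndarray
    fs: float
    lock: str
    baseline_ms: tuple
    ch_names: list[str]
    ch_types: list[str]
    trial_index: np.ndarray
    retained: np.ndarray = None
    reject_reason: list = None
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.lock not in ("stimulus", "response"):
            raise ValueError("lock must be 'stimulus' or 'response'")
        dt = np.diff(self.times_ms)
        if self.times_ms.size > 1 and not (
            np.all(dt > 0) and np.allclose(dt, 1000.0 / self.fs, rtol=1e-6)
        ):
            raise ValueError("time axis must increase uniformly at 1/fs")
        b0, b1 = self.baseline_ms
        tol = 500.0 / self.fs  # half a sample
        if not (self.times_ms[0] - tol <= b0 < b1 <= self.times_ms[-1] + tol):
            raise ValueError("baseline window must lie inside the epoch window")
        if self.retained is None:
            self.retained = np.ones(self.data.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, bool)
        if self.reject_reason is None:
            self.reject_reason = [""] * self.data.shape[0]
        self.trial_index = np.asarray(self.trial_index, int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]

    def picks(self, ch_type: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == ch_type],
                        dtype=int)

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.times_ms.copy(), self.fs, self.lock,
            tuple(self.baseline_ms), list(self.ch_names), list(self.ch_types),
            self.trial_index.copy(), self.retained.copy(),
            list(self.reject_reason), self.units,
        )


@dataclass
class Evoked:
    """Per-subject averaged waveform, channels x time."""

    data: np.ndarray
    times_ms: np.ndarray
    fs: float
    lock: str
    nave: int
    ch_names: list[str]
    ch_types: list[str]
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_times)")
        if self.nave < 1:
            raise ValueError("nave must be >= 1")

    def picks(self, ch_type: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == ch_type],
                        dtype=int)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.index(name)]

    def copy(self) -> "Evoked":
        return Evoked(self.data.copy(), self.times_ms.copy(), self.fs, self.lock,
                      self.nave, list(self.ch_names), list(self.ch_types), self.units)
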