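"""Electrode montages on an idealized spherical head.

Positions are stored as unit vectors (head frame: +x right, +y anterior,
+z superior) together with a physical sphere radius ``r_head_cm``.  Scalp
coordinates come from the standard 64-channel Biosemi 10-20 layout; four
periocular EOG electrodes are appended for ocular-artifact handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "build_montage"]

#: EOG electrode directions (unit vectors after normalization): above/below
#: the left eye and over the two outer canthi.
_EOG_POSITIONS = {
    "VEOGU": (-0.31, 0.93, 0.10),
    "VEOGL": (-0.31, 0.91, -0.22),
    "HEOGL": (-0.72, 0.62, -0.12),
    "HEOGR": (0.72, 0.62, -0.12),
}


@dataclass(frozen=True)
class Montage:
    """Labeled electrode set on the unit sphere.

    Parameters
    ----------
    labels : list of str
        Unique channel names, scalp channels first.
    positions : ndarray, shape (n_channels, 3)
        Unit-norm directions of each electrode.
    ch_types : list of str
        ``"eeg"`` or ``"eog"`` per channel.
    r_head_cm : float
        Radius of the sphere representing the head, in cm.
    """

    labels: list[str]
    positions: np.ndarray
    ch_types: list[str]
    r_head_cm: float = 10.0
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.labels) != pos.shape[0] or len(self.ch_types) != pos.shape[0]:
            raise ValueError("labels/positions/ch_types lengths differ")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not self.r_head_cm > 0:
            raise ValueError("r_head_cm must be positive")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must be unit-norm")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def scalp_picks(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == "eeg"])

    @property
    def eog_picks(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == "eog"])

    @property
    def scalp_labels(self) -> list[str]:
        return [self.labels[i] for i in self.scalp_picks]

    def index(self, label: str) -> int:
        """Channel index of ``label`` (KeyError if absent)."""
        return self._index[label]

    def positions_cm(self) -> np.ndarray:
        """Physical electrode coordinates in cm."""
        return self.positions * self.r_head_cm


def build_montage(layout_name: str = "biosemi64", r_head_cm: float = 10.0) -> Montage:
    """Build the standard montage used throughout the pipeline.

    The only supported layout is ``"biosemi64"``: the 64 scalp positions of
    the Biosemi 10-20 system (taken from :mod:`mne`'s idealized standard
    montage and projected onto the unit sphere) plus 4 EOG channels.

    Parameters
    ----------
    layout_name : str
        Layout identifier; only ``"biosemi64"`` is known.
    r_head_cm : float
        Physical sphere radius in cm (the study convention is 10 cm).

    Returns
    -------
    Montage
        68 labeled unit-sphere positions (64 EEG + 4 EOG).
    """
    if layout_name != "biosemi64":
        raise ValueError(
            f"unknown montage layout {layout_name!r}; supported: 'biosemi64'"
        )
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    ch_pos = std.get_positions()["ch_pos"]
    labels = list(ch_pos)
    pos = np.array([ch_pos[k] for k in labels], dtype=float)
    # project the idealized scalp coordinates onto the unit sphere
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    types = ["eeg"] * len(labels)
    for lab, p in _EOG_POSITIONS.items():
        labels.append(lab)
        p = np.asarray(p, float)
        pos = np.vstack([pos, p / np.linalg.norm(p)])
        types.append("eog")
    return Montage(labels=labels, positions=pos, ch_types=types, r_head_cm=r_head_cm)
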