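"""File I/O: EDF recordings, events tables, montage files and array
containers.

Continuous recordings are written as plain 16-bit EDF (readable by any
EDF tool; tests round-trip through an independent reader).  Events go to
a long-format TSV with columns ``onset_s, duration_s, trial_type,
trial_index, accuracy`` (``trial_type`` is ``stimulus`` or
``vocal_onset``).  Montages are whitespace-separated ``label x y z``
text.  Epochs/evoked/source estimates are stored as ``.npz`` arrays with
a JSON sidecar carrying the metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, Evoked, Recording, make_event_table
from .montage import _EOG_POSITIONS, Montage

__all__ = [
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
    "write_montage_txt",
    "read_montage_txt",
    "save_evoked",
    "load_evoked",
    "save_epochs",
    "load_epochs",
]


def _edf_field(value, width) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(v: float, width: int = 8) -> str:
    for fmt in (f"{v:.6g}", f"{v:.4g}", f"{v:.2g}", f"{v:.0f}"):
        if len(fmt) <= width:
            return fmt
    return fmt[:width]


def write_edf(path, rec: Recording, record_s: float = 1.0) -> None:
    """Write a recording as plain 16-bit EDF.

    The signal is split into 1 s data records; a partial final record is
    zero-padded (EDF stores whole records only), so readers may see up to
    one extra second of zeros at the end.
    """
    path = Path(path)
    n_ch = rec.n_channels
    spr = int(round(record_s * rec.fs))
    n_rec = int(np.ceil(rec.n_samples / spr))
    pmax = np.maximum(np.abs(rec.data).max(axis=1), 1.0) * 1.0005
    pmin = -pmax
    dmax, dmin = 32767, -32767

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field("X X X X", 80)
    hdr += _edf_field("Startdate X X X X", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (n_ch + 1), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(_fmt_float(record_s), 8)
    hdr += _edf_field(n_ch, 4)
    for field, width in (
        (rec.ch_names, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV"] * n_ch, 8),
        ([_fmt_float(v) for v in pmin], 8),
        ([_fmt_float(v) for v in pmax], 8),
        ([dmin] * n_ch, 8),
        ([dmax] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([spr] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ):
        for v in field:
            hdr += _edf_field(v, width)

    scale = (dmax - dmin) / (pmax - pmin)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            f.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF recording via mne (independent of the writer)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts
    names = raw.ch_names
    types = ["eog" if n in _EOG_POSITIONS else "eeg" for n in names]
    return Recording(data, raw.info["sfreq"], list(names), types)


def write_events_tsv(path, events: pd.DataFrame) -> None:
    """Long-format events TSV (one row per stimulus / vocal onset)."""
    rows = []
    for _, tr in events.iterrows():
        rows.append({"onset_s": tr["stimulus_onset_s"], "duration_s": 0.0,
                     "trial_type": "stimulus",
                     "trial_index": int(tr["trial_index"]),
                     "accuracy": tr["accuracy"]})
        if np.isfinite(tr["vocal_onset_s"]):
            rows.append({"onset_s": tr["vocal_onset_s"], "duration_s": 0.0,
                         "trial_type": "vocal_onset",
                         "trial_index": int(tr["trial_index"]),
                         "accuracy": tr["accuracy"]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    stim = long[long["trial_type"] == "stimulus"].set_index("trial_index")
    voc = long[long["trial_type"] == "vocal_onset"].set_index("trial_index")
    idx = stim.index.to_numpy()
    vocal = np.full(idx.size, np.nan)
    for j, ti in enumerate(idx):
        if ti in voc.index:
            vocal[j] = voc.loc[ti, "onset_s"]
    return make_event_table(stim["onset_s"].to_numpy(), vocal,
                            stim["accuracy"].tolist())


def write_montage_txt(path, montage: Montage) -> None:
    with open(path, "w") as f:
        f.write(f"# r_head_cm {montage.r_head_cm}\n")
        for lab, p in zip(montage.labels, montage.positions):
            f.write(f"{lab} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")


def read_montage_txt(path) -> Montage:
    r_head = 10.0
    labels, pos = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["r_head_cm"]:
                    r_head = float(parts[1])
                continue
            lab, x, y, z = line.split()
            labels.append(lab)
            pos.append([float(x), float(y), float(z)])
    types = ["eog" if lab in _EOG_POSITIONS else "eeg" for lab in labels]
    return Montage(labels=labels, positions=np.asarray(pos), ch_types=types,
                   r_head_cm=r_head)


def _write_sidecar(path, meta: dict) -> None:
    Path(path).with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))


def save_evoked(path, ev: Evoked) -> None:
    path = Path(path)
    np.savez(path, data=ev.data, times_ms=ev.times_ms)
    _write_sidecar(path, {"fs": ev.fs, "lock": ev.lock, "nave": ev.nave,
                          "ch_names": ev.ch_names, "ch_types": ev.ch_types,
                          "units": ev.units})


def load_evoked(path) -> Evoked:
    path = Path(path)
    arr = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return Evoked(data=arr["data"], times_ms=arr["times_ms"], fs=meta["fs"],
                  lock=meta["lock"], nave=meta["nave"],
                  ch_names=meta["ch_names"], ch_types=meta["ch_types"],
                  units=meta["units"])


def save_epochs(path, ep: EpochSet) -> None:
    path = Path(path)
    np.savez(path, data=ep.data, times_ms=ep.times_ms,
             trial_index=ep.trial_index, retained=ep.retained)
    _write_sidecar(path, {
        "fs": ep.fs, "lock": ep.lock, "baseline_ms": list(ep.baseline_ms),
        "ch_names": ep.ch_names, "ch_types": ep.ch_types, "units": ep.units,
        "reject_reason": list(ep.reject_reason),
    })


def load_epochs(path) -> EpochSet:
    path = Path(path)
    arr = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        data=arr["data"], times_ms=arr["times_ms"], fs=meta["fs"],
        lock=meta["lock"], baseline_ms=tuple(meta["baseline_ms"]),
        ch_names=meta["ch_names"], ch_types=meta["ch_types"],
        trial_index=arr["trial_index"], retained=arr["retained"],
        reject_reason=meta["reject_reason"], units=meta["units"],
    )
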